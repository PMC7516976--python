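"""DPD loss, estimation, information matrices and alpha selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from ingarch_dpd import (GEOMETRIC, POISSON, ContaminationSpec, DPDConfig,
                         ModelSpec, asymptotic_variance, contaminate,
                         dpd_gradient_terms, dpd_loss_term, dpd_objective,
                         fit_mdpde, negbin, select_alpha, simulate_ingarch)
from ingarch_dpd.mdpde import MDPDEFit, dpd_hessian_terms

FAMILIES = {"poisson": POISSON, "negbin": negbin(10), "geometric": GEOMETRIC}


# ---------------------------------------------------------------------------
# loss values against independent oracles


def test_loss_alpha0_is_negative_log_pmf():
    assert dpd_loss_term(0, 0.0, 0.0, POISSON) == pytest.approx(1.0, rel=1e-12)


def test_geometric_closed_form_series():
    # p = 0.5, alpha = 1: sum p^2(y) = 0.25 / (1 - 0.25); term = 1/3 - 2*0.5
    val = dpd_loss_term(1, np.log(0.5), 1.0, GEOMETRIC)
    assert val == pytest.approx(1 / 3 - 1.0, rel=1e-12)


def test_geometric_series_vs_truncation_paths():
    """Closed-form geometric power sums agree with forced truncation."""
    for eta in (-2.0, -0.7, -0.2):
        for alpha in (0.1, 0.5, 1.0):
            a = dpd_loss_term(2, eta, alpha, GEOMETRIC, power_sum_method="series")
            b = dpd_loss_term(2, eta, alpha, GEOMETRIC, power_sum_method="grid")
            assert a == pytest.approx(b, abs=1e-10)


def test_poisson_power_sum_vs_brute_force():
    """Adaptive truncation vs an explicit sum to y = 200."""
    alpha, eta, yobs = 1.0, 0.0, 0
    y = np.arange(0, 201)
    brute = np.sum(np.exp((1 + alpha) * (eta * y - np.exp(eta) - gammaln(y + 1))))
    expected = brute - (1 + 1 / alpha) * np.exp(alpha * (-np.exp(eta)))
    assert dpd_loss_term(yobs, eta, alpha, POISSON) == pytest.approx(
        expected, abs=1e-12)


def test_loss_rejects_negative_alpha():
    with pytest.raises(ValueError):
        dpd_loss_term(0, 0.0, -0.1, POISSON)


# ---------------------------------------------------------------------------
# objective and gradients


def test_objective_single_observation(poisson_model):
    val = dpd_objective([3], (1.0, 0.2, 0.2), 0.3, poisson_model, 2.0)
    assert val == pytest.approx(
        dpd_loss_term(3, np.log(2.0), 0.3, POISSON), rel=1e-12)


def test_cmle_objective_equals_plain_nll(poisson_model, poisson_series):
    """alpha=0 objective equals a straightforward loop NLL implementation."""
    y = poisson_series
    theta = (0.9, 0.25, 0.2)
    xt, s = float(y.mean()), 0.0
    for t in range(len(y)):
        s += xt - y[t] * np.log(xt) + gammaln(y[t] + 1)
        xt = theta[0] + theta[1] * xt + theta[2] * y[t]
    assert dpd_objective(y, theta, 0.0, poisson_model, float(y.mean())) == \
        pytest.approx(s / len(y), rel=1e-12)


@pytest.mark.parametrize("name", list(FAMILIES))
@pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
def test_gradient_terms_match_finite_differences(name, alpha):
    fam = FAMILIES[name]
    m = ModelSpec(fam)
    rng = np.random.default_rng(5)
    y = rng.integers(fam.support_min, fam.support_min + 6, size=50)
    theta = np.array([0.9, 0.3, 0.2])
    x_init = 2.5
    g = dpd_gradient_terms(y, theta, alpha, m, x_init).sum(axis=0)
    eps = 1e-6
    fd = np.empty(3)
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        fd[j] = (dpd_objective(y, theta + e, alpha, m, x_init)
                 - dpd_objective(y, theta - e, alpha, m, x_init)) / (2 * eps) * len(y)
    assert np.max(np.abs(g - fd) / np.maximum(1.0, np.abs(fd))) < 1e-6


@pytest.mark.parametrize("alpha", [0.2, 1.0])
def test_hessian_terms_match_finite_differences(alpha, poisson_model):
    rng = np.random.default_rng(9)
    y = rng.poisson(2.0, 60)
    theta = np.array([0.8, 0.25, 0.3])
    H = dpd_hessian_terms(y, theta, alpha, poisson_model, 2.0).sum(axis=0)
    eps = 1e-6
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        fd = (dpd_gradient_terms(y, theta + e, alpha, poisson_model, 2.0)
              - dpd_gradient_terms(y, theta - e, alpha, poisson_model, 2.0)
              ).sum(axis=0) / (2 * eps)
        assert np.max(np.abs(H[:, j] - fd) / np.maximum(1.0, np.abs(fd))) < 1e-5


def test_estimating_equations_continuous_at_alpha_zero(poisson_model,
                                                       poisson_series):
    """The DPD score converges to the likelihood score as alpha -> 0."""
    y = poisson_series[:300]
    theta = np.array([1.1, 0.15, 0.25])
    g0 = dpd_gradient_terms(y, theta, 0.0, poisson_model, float(y.mean()))
    g1 = dpd_gradient_terms(y, theta, 1e-6, poisson_model, float(y.mean()))
    assert np.max(np.abs(g0.mean(0) - g1.mean(0))) < 1e-4


def test_score_row_vanishes_at_conditional_mean(poisson_model):
    """alpha=0 Poisson: gradient row is -(Y - X)/X * dX/dtheta."""
    y = np.array([2, 2, 2, 2])
    theta = (2.0, 0.0, 0.0)  # X_t = 2 = Y_t for t >= 2
    G = dpd_gradient_terms(y, theta, 0.0, poisson_model, 2.0)
    assert np.allclose(G, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# fitting


def test_cmle_matches_independent_optimizer(poisson_model, fast_config):
    y, _ = simulate_ingarch(poisson_model, (1.0, 0.3, 0.3), 1000, seed=3)
    fit = fit_mdpde(y, 0.0, poisson_model, fast_config)
    assert not fit.boundary  # interior optimum, so the box-free oracle applies

    def nll(th):
        d, a, b = th
        xt, s = float(y.mean()), 0.0
        for t in range(len(y)):
            s += xt - y[t] * np.log(xt)
            xt = d + a * xt + b * y[t]
        return s / len(y)

    res = minimize(nll, [1.0, 0.3, 0.3], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10_000})
    assert np.max(np.abs(np.asarray(res.x) - fit.theta_hat)) < 1e-4
    assert fit.objective <= res.fun + gammaln(y + 1).mean() + 1e-8


def test_first_order_condition_at_interior_optimum(poisson_model, fast_config):
    y, _ = simulate_ingarch(poisson_model, (1.0, 0.3, 0.3), 800, seed=3)
    fit = fit_mdpde(y, 0.25, poisson_model, fast_config)
    assert fit.converged and not fit.boundary
    assert np.max(np.abs(fit.per_t_grad.sum(axis=0))) < 1e-5 * fit.n_obs


def test_iid_limit_recovers_sample_mean(poisson_model, fast_config):
    """With a = b = 0 truth the fit collapses to the iid-Poisson solution.

    For iid data the feedback coefficient `a` is unidentified (any a with
    b = 0 and d = mean*(1-a) gives the same stationary intensity), so the
    informative checks are b-hat ~ 0 and the implied mean d/(1-a-b).
    """
    rng = np.random.default_rng(21)
    y = rng.poisson(3.0, 1500)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # boundary pinning ok
        fit = fit_mdpde(y, 0.0, poisson_model, fast_config)
    assert fit.theta_hat[2] < 0.05
    implied_mean = fit.theta_hat[0] / (1 - fit.theta_hat[1] - fit.theta_hat[2])
    assert implied_mean == pytest.approx(y.mean(), rel=0.05)


def test_parameter_recovery_is_unbiased(poisson_model, fast_config):
    """Monte-Carlo mean of theta-hat lands within 3 MC SE of the truth."""
    theta0 = np.array([1.0, 0.2, 0.2])
    reps, n = 60, 800
    for alpha in (0.0, 0.5):
        est = np.empty((reps, 3))
        for i in range(reps):
            y, _ = simulate_ingarch(poisson_model, theta0, n, seed=1000 + i)
            est[i] = fit_mdpde(y, alpha, poisson_model, fast_config).theta_hat
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0) - theta0) < 3 * se)


def test_robustness_ordering_under_contamination(poisson_model, fast_config):
    """Median estimation error at alpha=0.5 beats the CMLE on outliers."""
    theta0 = np.array([1.0, 0.2, 0.2])
    spec = ContaminationSpec(p=0.03, gamma=10.0)
    reps, n = 100, 500
    err = {0.0: [], 0.5: []}
    for i in range(reps):
        y, _ = simulate_ingarch(poisson_model, theta0, n, seed=5000 + i)
        yc = contaminate(y, spec, seed=9000 + i)
        for alpha in err:
            fit = fit_mdpde(yc, alpha, poisson_model, fast_config)
            err[alpha].append(np.linalg.norm(fit.theta_hat - theta0))
    assert np.median(err[0.5]) < np.median(err[0.0])


def test_fit_rejects_short_series(poisson_model):
    with pytest.raises(ValueError):
        fit_mdpde([1, 2, 3], 0.1, poisson_model)


# ---------------------------------------------------------------------------
# information matrices and sandwich variance


def test_information_identity_at_alpha_zero(poisson_model, fast_config):
    y, _ = simulate_ingarch(poisson_model, (1.0, 0.2, 0.3), 6000, seed=17)
    fit = fit_mdpde(y, 0.0, poisson_model, fast_config)
    rel = np.abs(fit.J_hat - fit.K_hat) / np.maximum(np.abs(fit.J_hat), 1e-3)
    assert np.max(rel) < 0.15
    assert np.allclose(fit.J_hat, fit.J_hat.T, atol=1e-10)
    # K_hat is PSD by construction
    assert np.min(np.linalg.eigvalsh(fit.K_hat)) > -1e-12


def test_sandwich_identity_algebra(poisson_model):
    fit = MDPDEFit(theta_hat=np.zeros(3), alpha=0.1, objective=0.0,
                   per_t_grad=np.zeros((10, 3)), J_hat=np.eye(3),
                   K_hat=np.eye(3), as_var=np.empty(0), converged=True,
                   n_obs=10, model=poisson_model, x_init=1.0)
    V = asymptotic_variance(fit)
    # (nI)^-1 (nI) (nI)^-1 = I/n
    assert np.allclose(V, np.eye(3) / 10)


def test_standard_errors_shrink_like_root_n(poisson_model, fast_config):
    theta0 = (1.0, 0.2, 0.2)
    ns = [250, 500, 1000, 2000]
    mean_se = []
    for n in ns:
        ses = []
        for i in range(8):
            y, _ = simulate_ingarch(poisson_model, theta0, n, seed=300 + i)
            ses.append(fit_mdpde(y, 0.25, poisson_model, fast_config).se[0])
        mean_se.append(np.mean(ses))
    slope = np.polyfit(np.log(ns), np.log(mean_se), 1)[0]
    assert -0.6 < slope < -0.4


def test_wald_interval_coverage_for_intercept(poisson_model, fast_config):
    theta0 = (1.0, 0.2, 0.2)
    reps, n, hits = 300, 500, 0
    for i in range(reps):
        y, _ = simulate_ingarch(poisson_model, theta0, n, seed=40_000 + i)
        fit = fit_mdpde(y, 0.2, poisson_model, fast_config)
        lo = fit.theta_hat[0] - 1.96 * fit.se[0]
        hi = fit.theta_hat[0] + 1.96 * fit.se[0]
        hits += lo <= theta0[0] <= hi
    assert 0.90 <= hits / reps <= 0.98


# ---------------------------------------------------------------------------
# alpha selection


def test_select_alpha_table_and_efficiency_loss(poisson_model, fast_config):
    """On clean data the sandwich-variance part of the AMSE criterion grows
    with alpha (efficiency loss); alpha=0 is tabulated but never selected
    by default."""
    y, _ = simulate_ingarch(poisson_model, (1.0, 0.2, 0.2), 2000, seed=1)
    grid = (0.1, 0.25, 0.5, 0.75, 1.0)
    alpha_star, table = select_alpha(y, poisson_model, grid, fast_config)
    assert 0.0 in table["alpha"].values and alpha_star > 0
    traces = [np.trace(fit_mdpde(y, a, poisson_model, fast_config).as_var)
              for a in (0.0,) + grid]
    assert np.all(np.diff(traces) > 0)


def test_amse_criterion_flags_cmle_under_contamination(poisson_model,
                                                       fast_config):
    """Additive outliers inflate the estimated AMSE of the CMLE relative to
    a moderate alpha (the pattern behind data-driven robust tuning)."""
    spec = ContaminationSpec(p=0.05, gamma=10.0)
    wins = 0
    for i in range(20):
        y, _ = simulate_ingarch(poisson_model, (1.0, 0.2, 0.2), 500,
                                seed=600 + i)
        yc = contaminate(y, spec, seed=700 + i)
        _, tab = select_alpha(yc, poisson_model, (0.25, 1.0), fast_config)
        t0 = float(tab.loc[tab.alpha == 0.0, "trace_amse"].iloc[0])
        t25 = float(tab.loc[tab.alpha == 0.25, "trace_amse"].iloc[0])
        wins += t0 > t25
    assert wins >= 14
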