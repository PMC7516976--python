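"""CUSUM-type change-point tests built on DPD loss gradients.

The null hypothesis is that the intensity parameter ``theta`` is constant
over the whole series.  With ``g_t = d l_t(theta_hat) / d theta`` the
per-``k`` process is the normalised quadratic form of the gradient partial
sums ``S_k = sum_{t<=k} g_t``:

    D_k = (1/n) S_k^T  Khat^{-1}  S_k ,

where ``Khat`` is the average score outer product.  The test statistic is
``max_k D_k``, which converges under the null to the supremum of the squared
Euclidean norm of a d-dimensional standard Brownian bridge; the level-0.05
critical value for three parameters is 3.004.  The classical score-based
CUSUM comparator is the ``alpha = 0`` version normalised by the observed
information ``Ihat_n`` (average loss Hessian) instead of ``Khat``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import linalg

from .families import ModelSpec
from .mdpde import DPDConfig, MDPDEFit, dpd_hessian_terms, fit_mdpde

__all__ = [
    "TestResult",
    "CriticalValueTable",
    "gradient_partial_sums",
    "cusum_process",
    "dpd_test",
    "score_cusum_test",
    "critical_value",
    "simulate_bb_sup",
    "load_critical_value_table",
]


@dataclass
class TestResult:
    """Outcome of a change-point test on one series."""

    statistic: float
    process: np.ndarray
    alpha: float
    critical_value: float
    level: float
    reject: bool
    change_index: int
    variant: str
    fit: MDPDEFit | None = None

    def process_table(self) -> np.ndarray:
        """Two-column (k, D_k) array for plotting the per-k process."""
        k = np.arange(1, self.process.size + 1)
        return np.column_stack([k, self.process])


def gradient_partial_sums(per_t_grad: np.ndarray) -> np.ndarray:
    """Cumulative row sums ``S_k`` of the per-observation gradients."""
    G = np.asarray(per_t_grad, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite gradient rows")
    return np.cumsum(G, axis=0)


def cusum_process(per_t_grad: np.ndarray, normalizer: np.ndarray) -> np.ndarray:
    """The per-k quadratic-form process ``(1/n) S_k^T M^{-1} S_k``."""
    S = gradient_partial_sums(per_t_grad)
    n = S.shape[0]
    if np.linalg.cond(normalizer) > 1e12:
        raise linalg.LinAlgError("normalizer matrix is numerically singular")
    sol = linalg.solve(normalizer, S.T, assume_a="sym")
    proc = np.einsum("kd,dk->k", S, sol) / n
    return np.maximum(proc, 0.0)


def _result_from_process(proc, alpha, level, crit, variant, fit):
    k_star = int(np.argmax(proc)) + 1  # first argmax, 1-based
    stat = float(proc[k_star - 1])
    return TestResult(
        statistic=stat, process=proc, alpha=alpha, critical_value=crit,
        level=level, reject=bool(stat > crit), change_index=k_star,
        variant=variant, fit=fit,
    )


def dpd_test(y, alpha: float, model: ModelSpec, level: float = 0.05,
             config: DPDConfig | None = None, x_init: float | None = None,
             fit: MDPDEFit | None = None) -> TestResult:
    """DPD-based robust change-point test at tuning constant ``alpha``.

    Fits the MDPDE on the full series (unless a fit is supplied), forms the
    per-k process in the ``Khat`` metric and compares the maximum against the
    Brownian-bridge critical value for ``model.dim`` parameters.  The change
    location estimate is the (first) maximiser of the process.
    """
    if fit is None:
        fit = fit_mdpde(y, alpha, model, config, x_init)
    if not fit.converged:
        raise RuntimeError("MDPDE fit did not converge; test unreliable")
    proc = cusum_process(fit.per_t_grad, fit.K_hat)
    crit = critical_value(model.dim, level)
    return _result_from_process(proc, float(alpha), level, crit, "dpd", fit)


def score_cusum_test(y, model: ModelSpec, level: float = 0.05,
                     config: DPDConfig | None = None,
                     x_init: float | None = None,
                     fit: MDPDEFit | None = None) -> TestResult:
    """Score-vector CUSUM test: the ``alpha = 0`` construction with the
    observed information ``Ihat_n`` as normalizer."""
    if fit is None:
        fit = fit_mdpde(y, 0.0, model, config, x_init)
    elif fit.alpha != 0.0:
        raise ValueError("score test requires the alpha=0 (CMLE) fit")
    if not fit.converged:
        raise RuntimeError("CMLE fit did not converge; test unreliable")
    # J_hat is already the average analytic Hessian of the alpha=0 loss
    I_n = fit.J_hat
    proc = cusum_process(fit.per_t_grad, I_n)
    crit = critical_value(model.dim, level)
    return _result_from_process(proc, 0.0, level, crit, "score", fit)


# ---------------------------------------------------------------------------
# Brownian-bridge critical values


def simulate_bb_sup(dim: int, grid_size: int = 2000, reps: int = 100_000,
                    seed: int = 0, probs=(0.90, 0.95, 0.99),
                    chunk: int = 512) -> dict[float, float]:
    """Monte-Carlo quantiles of ``sup_s ||B_d(s)||^2`` for a standard
    d-dimensional Brownian bridge.

    Each replicate builds ``dim`` Gaussian random walks on ``grid_size``
    points scaled by ``1/sqrt(grid_size)``, bridges them as
    ``W(s) - s W(1)`` and records the maximum squared norm.  Chunked over
    replicates to bound memory; reproducible from ``seed``.
    """
    if dim < 1 or grid_size < 2 or reps < 1:
        raise ValueError("invalid simulation size")
    rng = np.random.default_rng(seed)
    s = np.arange(1, grid_size + 1) / grid_size
    sups = np.empty(reps)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        z = rng.standard_normal((m, dim, grid_size))
        w = np.cumsum(z, axis=2)
        w /= np.sqrt(grid_size)
        bridge = w - s[None, None, :] * w[:, :, -1:]
        sq = np.einsum("mdk,mdk->mk", bridge, bridge)
        sups[done:done + m] = sq.max(axis=1)
        done += m
    return {float(p): float(np.quantile(sups, p)) for p in probs}


@dataclass(frozen=True)
class CriticalValueTable:
    """Shipped quantile table of ``sup ||B_d||^2`` by dimension and level."""

    values: dict[int, dict[float, float]]
    reps: int
    grid_size: int
    seed: int

    def lookup(self, dim: int, level: float) -> float:
        if dim not in self.values:
            raise KeyError(
                f"no tabulated critical values for dim={dim}; "
                "use simulate_bb_sup"
            )
        row = self.values[dim]
        for lv, v in row.items():
            if abs(lv - level) < 1e-12:
                return v
        raise KeyError(
            f"level {level} not tabulated (have {sorted(row)}); "
            "use simulate_bb_sup for other levels"
        )


_TABLE_CACHE: CriticalValueTable | None = None


def load_critical_value_table() -> CriticalValueTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        raw = json.loads(
            resources.files("ingarch_dpd.data").joinpath("bb_sup_quantiles.json")
            .read_text()
        )
        # JSON keys are upper-tail probabilities, i.e. levels
        values = {
            int(d): {float(p): v for p, v in row.items()}
            for d, row in raw["values"].items()
        }
        _TABLE_CACHE = CriticalValueTable(
            values=values, reps=raw["reps"], grid_size=raw["grid_size"],
            seed=raw["seed"],
        )
    return _TABLE_CACHE


def critical_value(dim: int, level: float = 0.05,
                   simulate: bool = False, **sim_kwargs) -> float:
    """Level-``level`` critical value of the limiting null distribution.

    By default looks up the shipped simulated table (dims 1-6, levels
    0.10/0.05/0.01); with ``simulate=True`` runs :func:`simulate_bb_sup`
    for arbitrary dimensions and levels.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if simulate:
        q = simulate_bb_sup(dim, probs=(1.0 - level,), **sim_kwargs)
        return q[1.0 - level]
    return load_critical_value_table().lookup(dim, level)
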