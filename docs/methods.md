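# Methods

## Model class

Observations are counts `Y_1, …, Y_n` whose conditional law given the past
is a one-parameter exponential family

```
p(y | η) = exp{η·y − A(η)} h(y),    B = A′,  B′ = A″,
```

so `B(η_t)` and `B′(η_t)` are the conditional mean and variance. Three
members are implemented:

| family | η(x) | A(η) | support | notes |
|---|---|---|---|---|
| Poisson | log x | e^η | 0,1,… | mean = variance |
| negative binomial | log(x/(x+r)) | −r·log(1−e^η) | 0,1,… | failures before the r-th success; `r` is a known model input, never estimated |
| geometric (trials) | log(1−1/x) | η − log(1−e^η) | 1,2,… | total trials to first success, mean 1/p — suited to return-time data where `Y_t ≥ 1` |

The conditional mean follows a feedback recursion: linear INGARCH(1,1),
`X_t = d + a·X_{t−1} + b·Y_{t−1}`, or its threshold variant with separate
slopes above/below an integer level `l`. Stationarity/ergodicity needs
`a + b < 1` (threshold: `a + max(b1,b2) < 1`); the fitted parameter region
enforces `d ∈ [d_low, d_high]` and `a + max(b) ≤ 1 − ε` with wide defaults
`d_low = 1e−4`, `d_high = 1e4`, `ε = 1e−3`. These are numerical guards
shaping a compact region, not modelling choices.

Since the pre-sample history is unobserved, estimation runs the recursion
from an arbitrary start `X̃_1`. The default is the sample mean of the series
(`d/(1−a)` is available as an override). The start is treated as free of
`θ`, i.e. the derivative filters begin at zero: initialization effects decay
geometrically, and this keeps the filter a pure function of the data. (A
θ-dependent start would change nothing asymptotically but make the filter
state depend on the parameter point in a way that complicates caching.)

All filters — `X̃_t`, `∂X̃_t/∂θ`, `∂²X̃_t/∂θ∂θ′` — are linear recursions
with common AR coefficient `a` and are evaluated by `scipy.signal.lfilter`;
the Hessian recursion has non-zero entries only in the row/column of `a`.

## Estimation

The density-power-divergence loss per observation is

```
l_t(θ) = Σ_y p^{1+α}(y|η̃_t) − (1 + 1/α)·p^α(Y_t|η̃_t)     (α > 0),
l_t(θ) = −log p(Y_t|η̃_t)                                   (α = 0),
```

with `η̃_t = B⁻¹(X̃_t(θ))`. The MDPDE minimises the average loss; `α = 0`
recovers the conditional MLE, `α = 1` an L2-type estimator. The gradient and
Hessian in `η` are analytic:

```
∂l/∂η  = (1+α)[Σ p^{1+α}(y−B) − p^α(Y)(Y−B)]
∂²l/∂η² = (1+α)[(1+α)Σ p^{1+α}(y−B)² − B′Σ p^{1+α} − α p^α(Y)(Y−B)² + B′p^α(Y)]
```

and are chained through `η = B⁻¹(x)` (`dη/dx = 1/B′`,
`d²η/dx² = −B″/B′³`) to θ-space.

**Power sums.** The support sums `Σ_y p^{1+α}(y|η)·(y−B)^k`, k = 0,1,2, are
closed-form geometric series for the trials-geometric family. For Poisson
and negative binomial they are evaluated on a shared grid
`y = support_min … y_max`, with `y_max` the inverse survival function of the
family at `0.01 × tol` (tol default 1e−12) evaluated at the largest filtered
mean, capped at `mean + 50·sd + 100` (an error if the cap binds, which the
exponential tails prevent in practice). The truncation path and the
geometric closed form agree to 1e−10 on forced comparisons.

**Optimisation.** SLSQP with analytic gradients on the box, plus the linear
constraint `a + max(b) ≤ 1 − ε`; tiny line-search violations are projected
back before evaluation. Starting points: one moment-matched start
(`a = b = 0.2`, `d = ȳ(1 − a − b)`, the stationary-mean identity) plus
seeded uniform draws from a shrunken feasible box (`n_multistart = 5` by
default; the Monte-Carlo harness uses a single start since the clean/
contaminated study settings are well behaved and the moment start is
consistent). Best objective wins; boundary-pinned solutions are flagged with
a warning, non-convergence is flagged, not raised. Objective/gradient pairs
are cached per parameter point because SLSQP requests them separately.

**Inference.** `K̂ = n⁻¹Σ g_t g_t′` (score outer products) and
`Ĵ = n⁻¹Σ H_t` (analytic loss Hessians, symmetrised). The covariance of
`θ̂` is the sandwich `(ΣH_t)⁻¹(Σg_t g_t′)(ΣH_t)⁻¹`, whose diagonal roots
are the reported standard errors. Note this mixes an n-scaled variance with
the n-free squared-bias term in the AMSE tuning criterion below; the
criterion is implemented exactly in that form, so its balance point depends
on `n`. Matrix solves are symmetric solves with a condition-number guard of
1e12.

**Choosing α.** For each candidate, `trace[(θ̂_α−θ̂_1)(θ̂_α−θ̂_1)′ +
As.var(θ̂_α)]` with the `α = 1` fit as pilot (refit per dataset, never
cached across series); the default grid is 0.05–1.00 in steps of 0.05, with
`α = 0` tabulated for reference but excluded from the argmin unless
requested. Because the pilot has zero estimated bias by construction, the
argmin is diffuse on clean data; the criterion is most informative through
the *contrast* of its curve between clean and contaminated samples, which is
what the tests assert.

## Change-point test

With `S_k = Σ_{t≤k} g_t` at the full-sample fit, the per-k process is
`D_k = (1/n)·S_k′ K̂⁻¹ S_k` and the statistic `max_{1≤k≤n} D_k` (identical
algebraically to the mean-gradient form `(k²/n)·∇L̄_k′ K̂⁻¹ ∇L̄_k`). The max
runs over the full range k = 1…n — early-k terms are negligible through the
weighting, so no trimming is applied. Ties in the argmax (the change-location
estimate) break to the first index. `K̂` is always evaluated at the
full-series fit; there is no recursive/monitoring variant. The score-based
CUSUM comparator is the `α = 0` construction normalised by the observed
information `Î_n = n⁻¹Σ ∂²l_{0,t}/∂θ∂θ′` instead of `K̂_0`; both are
exposed, and on clean data they agree asymptotically (information identity).

Critical values are quantiles of `sup_{0≤s≤1}‖B°_d(s)‖²`. A table for
d = 1–6 at levels 0.10/0.05/0.01 ships with the package, generated once by
Monte Carlo (200 000 replicates, 2000-point grid, seed 20200424 + d;
regenerate with `scripts/generate_critvals.py`). The simulation builds d
independent scaled Gaussian random walks, bridges them as `W(s) − s·W(1)`
and records the max squared norm. At d = 3, level 0.05 the table gives
3.0065, matching the published reference value 3.004. Note the gridded sup
is biased low by roughly `2‖B‖·0.5826/√N` (the usual discrete-monitoring
continuity effect); at N = 2000 and d = 1 this is ≈ 0.035, which is why the
d = 1 entry (1.8029) sits below the continuum Kolmogorov value
`1.3581² = 1.8444`. Comparisons against the continuum value therefore use a
finer grid (N ≥ 20 000), where the bias is within Monte-Carlo noise.

## Synthetic data and the Monte-Carlo harness

`simulate_ingarch` draws the recursion forward on the sampled counts,
starting at `X_1 = 0` (the first draw is then degenerate at the support
floor — Poisson(0) = 0 — matching the study design; a non-zero start is a
parameter). A mid-sample parameter change switches the transition into
observation `⌊n/2⌋+1` onward, with the intensity carried continuously
across the switch (restarting it is the other reading of "changes at
t = [n/2]"; carrying is the conservative choice and is documented
behaviour). Contamination is `Yc_t = Y_t + P_t·Yo_t` with
`P_t ~ Bernoulli(p)` and iid Poisson(γ) or NB(r = 10, κ) outlier sizes, all
independent of the clean series.

`run_experiment` runs one cell (model, θ0, optional θ1, optional
contamination, n, reps): per replicate it simulates, contaminates, sets
`X̃_1` to the sample mean, and runs the score test and the DPD test per
requested α at level 0.05 (critical value 3.004 for 3-parameter models).
Per-replicate seeds are spawned from the cell seed via `SeedSequence`, so
results are independent of any partitioning of replicates. Failed replicates
are dropped and counted; cells with > 5 % failures are flagged. Outputs are
tidy tables with rejection counts, rates and binomial MC standard errors.

What the generator does *not* emulate: real count series have covariate
effects, seasonality, over-dispersion beyond the chosen family, and outliers
that are neither Bernoulli-timed nor additive. Passing the harness therefore
shows correctness of the estimator/test implementation under the stated
data-generating processes, not real-world fit.

`return_times` turns a real-valued series (e.g. log-returns) into the count
series of gaps between successive exits from the empirical
`(q_low, q_high)` quantile band (linear-interpolation quantiles of the full
series, strict exceedance; both conventions configurable). With `τ_0 = 0`
the first gap is the first hitting index; `drop_first` discards it. Such gap
series are ≥ 1 by construction, which is why the trials-geometric family is
provided.

## Problem sizes and numerical choices

The shipped study sizes mirror the published design at 500 replicates per
cell (n ∈ {500, 1000}), which resolves rejection rates to a binomial SE of
about 0.01–0.02 and completes in about a minute per cell on one core; the
critical-value reproduction uses 100 000 bridge replicates on a 2000-point
grid. Loss sums truncate at tail mass 1e−12; optimizer ftol 1e−10, max 200
iterations; derivative correctness is enforced by finite-difference tests at
1e−6 (gradients) and 1e−5 (Hessians).

Known limitations: first-order (p = q = 1) recursions only; no covariates;
no zero-inflated families; single change point under the alternative; `r`
of the negative binomial must be known; for iid-like data (`a + b ≈ 0`) the
feedback coefficient `a` is unidentified along the ridge `b = 0,
d = μ(1−a)`, so only `b` and the implied mean are interpretable there.
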