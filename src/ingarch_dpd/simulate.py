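"""Data generators, outlier contamination and the size/power harness.

The generators draw INGARCH-type series with the recursion advanced on the
*drawn* counts, optionally switching the parameter vector mid-sample (the
intensity recursion is carried continuously across the switch).  Additive
outlier contamination follows

    Yc_t = Y_t + P_t * Yo_t,

with ``P_t ~ Bernoulli(p)`` and iid count-valued outlier magnitudes
``Yo_t`` (Poisson or negative binomial), all independent of the clean
series.  ``run_experiment`` wraps the whole Monte-Carlo loop used to study
empirical size and power of the score CUSUM and DPD tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .changepoint import dpd_test, score_cusum_test
from .families import FamilySpec, ModelSpec
from .mdpde import DPDConfig, fit_mdpde

__all__ = [
    "ContaminationSpec",
    "ExperimentConfig",
    "simulate_ingarch",
    "contaminate",
    "run_experiment",
    "return_times",
]


@dataclass(frozen=True)
class ContaminationSpec:
    """Additive-outlier contamination: Bernoulli(p) times an iid count."""

    p: float
    outlier_family: str = "poisson"  # or "negbin"
    gamma: float = 10.0              # Poisson outlier mean
    r: int = 10                      # negbin outlier size
    kappa: float = 0.5               # negbin outlier success probability

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.outlier_family not in ("poisson", "negbin"):
            raise ValueError(f"unknown outlier family {self.outlier_family!r}")
        if self.outlier_family == "poisson" and self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.outlier_family == "negbin" and not (0 < self.kappa <= 1 and self.r >= 1):
            raise ValueError("invalid negbin outlier parameters")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        P = rng.random(n) < self.p
        if self.outlier_family == "poisson":
            Yo = rng.poisson(self.gamma, size=n)
        else:
            Yo = rng.negative_binomial(self.r, self.kappa, size=n)
        return P * Yo


def simulate_ingarch(model: ModelSpec, theta, n: int, seed=None,
                     x1: float = 0.0, theta1=None, change_index: int | None = None):
    """Draw an INGARCH/INTGARCH series of length ``n``.

    ``X_1 = x1`` (0 by default, making the first draw degenerate at the
    support floor), then ``Y_t`` is drawn from the family at mean ``X_t``
    and the recursion is advanced on the drawn count.  If ``theta1`` is
    given, the parameter switches to it for ``t > change_index`` (default
    ``n // 2``) with the intensity carried through the change.

    Returns ``(y, x)``: the counts and the conditional means.
    """
    theta = model.check_theta(theta)
    if theta1 is not None:
        theta1 = model.check_theta(theta1)
        if change_index is None:
            change_index = n // 2
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam = model.family
    y = np.empty(n, dtype=np.int64)
    x = np.empty(n, dtype=float)
    xt = float(x1)
    d, a = theta[0], theta[1]
    b = theta[2:]
    for t in range(n):
        x[t] = xt
        y[t] = fam.sample(rng, xt)
        # observations after the change point are generated under theta1,
        # with the intensity recursion carried continuously across the switch
        if theta1 is not None and t + 1 == change_index:
            d, a, b = theta1[0], theta1[1], theta1[2:]
        xt = d + a * xt + float(model.regressors(y[t:t + 1])[0] @ b)
    return y, x


def contaminate(y, spec: ContaminationSpec, seed=None) -> np.ndarray:
    """Apply ``Yc = Y + P * Yo`` with a fresh random stream."""
    y = np.asarray(y, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return y + spec.draw(rng, y.size)


@dataclass(frozen=True)
class ExperimentConfig:
    """One Monte-Carlo cell of the size/power study."""

    model: ModelSpec
    theta0: tuple
    n: int
    reps: int = 1000
    theta1: tuple | None = None
    alphas: tuple = (0.1, 0.2, 0.3, 0.5, 1.0)
    level: float = 0.05
    contamination: ContaminationSpec | None = None
    include_score: bool = True
    seed: int = 0
    x1: float = 0.0
    fit_config: DPDConfig = field(default_factory=lambda: DPDConfig(n_multistart=1))

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0,1)")


def _one_replicate(cfg: ExperimentConfig, rep_seed: np.random.SeedSequence):
    """Simulate, contaminate, and run every requested test on one series."""
    rng = np.random.default_rng(rep_seed)
    y, _ = simulate_ingarch(cfg.model, cfg.theta0, cfg.n, seed=rng,
                            x1=cfg.x1, theta1=cfg.theta1)
    if cfg.contamination is not None:
        y = contaminate(y, cfg.contamination, seed=rng)
    x_init = float(np.mean(y))
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if cfg.include_score:
            res = score_cusum_test(y, cfg.model, cfg.level, cfg.fit_config,
                                   x_init=x_init)
            out["score"] = (res.reject, res.change_index)
        for a in cfg.alphas:
            res = dpd_test(y, a, cfg.model, cfg.level, cfg.fit_config,
                           x_init=x_init)
            out[f"dpd_{a:g}"] = (res.reject, res.change_index)
    return out


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Monte-Carlo rejection rates for one parameter setting.

    Per-replicate seeds are spawned from ``cfg.seed`` so results do not
    depend on how replicates would be partitioned.  Replicates whose fit
    fails are dropped and counted; a cell with more than 5% failures is
    flagged.

    Returns a tidy DataFrame with one row per test variant: estimator,
    alpha, replicate counts, rejection rate and its binomial Monte-Carlo
    standard error, plus the mean relative change location among
    rejections.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.reps)
    records: dict[str, list] = {}
    failures = 0
    for ss in seeds:
        try:
            res = _one_replicate(cfg, ss)
        except Exception:
            failures += 1
            continue
        for key, val in res.items():
            records.setdefault(key, []).append(val)
    if not records:
        raise RuntimeError(
            f"all {cfg.reps} replicates failed; check the configuration"
        )
    rows = []
    for key, vals in records.items():
        rej = np.array([v[0] for v in vals], dtype=bool)
        loc = np.array([v[1] for v in vals], dtype=float) / cfg.n
        m = rej.size
        rate = float(rej.mean()) if m else np.nan
        rows.append({
            "estimator": "score" if key == "score" else "dpd",
            "alpha": 0.0 if key == "score" else float(key.split("_")[1]),
            "n": cfg.n,
            "reps": m,
            "failures": failures,
            "rejections": int(rej.sum()),
            "rate": rate,
            "mc_se": float(np.sqrt(max(rate * (1 - rate), 0.0) / m)) if m else np.nan,
            "mean_change_frac": float(loc[rej].mean()) if rej.any() else np.nan,
            "flagged": failures > 0.05 * cfg.reps,
        })
    return pd.DataFrame(rows)


def return_times(x, q_low: float = 0.05, q_high: float = 0.95,
                 drop_first: bool = False) -> np.ndarray:
    """Return times of extreme events of a real-valued series.

    Hitting times ``tau_1 < tau_2 < ...`` are the 1-based indices where the
    series falls strictly below its empirical ``q_low`` quantile or strictly
    above its ``q_high`` quantile (linear-interpolation quantiles of the
    full series).  The output is the gap series ``Y_t = tau_t - tau_{t-1}``
    with ``tau_0 = 0``, so every entry is at least 1 and the entries sum to
    the last hitting index.  ``drop_first=True`` discards the first gap.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d series of length >= 2")
    if not q_low < q_high:
        raise ValueError("need q_low < q_high")
    lo, hi = np.quantile(x, [q_low, q_high])
    taus = np.flatnonzero((x < lo) | (x > hi)) + 1
    if taus.size == 0:
        warnings.warn("no extreme events at the requested quantiles",
                      RuntimeWarning, stacklevel=2)
        return np.empty(0, dtype=np.int64)
    y = np.diff(np.concatenate([[0], taus])).astype(np.int64)
    return y[1:] if drop_first else y
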