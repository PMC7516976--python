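"""One-parameter exponential families and conditional-intensity recursions.

The observation model is a count process ``Y_t | F_{t-1} ~ p(y | eta_t)`` with

    p(y | eta) = exp{eta * y - A(eta)} h(y),

where ``eta`` is the natural parameter, ``B = A'`` maps it to the conditional
mean and ``B' = A''`` to the conditional variance.  The conditional mean
``X_t`` follows a GARCH-like feedback recursion ("INGARCH"):

    linear     X_t = d + a * X_{t-1} + b * Y_{t-1}
    threshold  X_t = d + a * X_{t-1} + b1 * max(Y_{t-1} - l, 0)
                                     + b2 * min(Y_{t-1}, l)

Given data and a parameter vector, the recursion started from an arbitrary
``x_init`` yields the approximated intensity ``X~_t(theta)`` together with its
first and second derivatives in ``theta``, which everything downstream
(estimation, sandwich variances, CUSUM statistics) is built from.  Because the
recursions are linear with a common AR coefficient ``a`` they are evaluated
with :func:`scipy.signal.lfilter` rather than Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special, stats

__all__ = [
    "FamilySpec",
    "ModelSpec",
    "FilterState",
    "POISSON",
    "GEOMETRIC",
    "negbin",
    "natural_param",
    "pmf",
    "log_pmf",
    "mean_var",
    "intensity_filter",
    "intensity_derivatives",
]


@dataclass(frozen=True)
class FamilySpec:
    """A one-parameter exponential family for counts.

    Supported members:

    - ``poisson``: mean ``e^eta``, support {0, 1, ...}.
    - ``negbin``: number of failures before the ``r``-th success, ``r`` known;
      ``eta = log(1 - p)``, support {0, 1, ...}.
    - ``geometric_trials``: number of Bernoulli trials up to and including the
      first success (so the mean is ``1/p`` and the support starts at 1);
      ``eta = log(1 - p)``.
    """

    name: str
    r: int | None = None

    def __post_init__(self) -> None:
        if self.name not in ("poisson", "negbin", "geometric_trials"):
            raise ValueError(f"unknown family {self.name!r}")
        if self.name == "negbin":
            if self.r is None or int(self.r) < 1:
                raise ValueError("negbin requires a known positive integer r")
        elif self.r is not None:
            raise ValueError(f"r is only meaningful for negbin, got {self.name}")

    # ---- support -------------------------------------------------------
    @property
    def support_min(self) -> int:
        return 1 if self.name == "geometric_trials" else 0

    @property
    def mean_floor(self) -> float:
        """Strict lower bound of the valid conditional-mean range."""
        return 1.0 if self.name == "geometric_trials" else 0.0

    def _check_eta(self, eta: np.ndarray) -> None:
        if self.name != "poisson" and np.any(eta >= 0):
            raise ValueError(f"{self.name} requires eta < 0")
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite natural parameter")

    # ---- canonical functions ------------------------------------------
    def A(self, eta):
        """Log-partition function."""
        eta = np.asarray(eta, dtype=float)
        self._check_eta(eta)
        if self.name == "poisson":
            return np.exp(eta)
        if self.name == "negbin":
            return -self.r * np.log1p(-np.exp(eta))
        # geometric_trials: A = eta - log(1 - e^eta)
        return eta - np.log1p(-np.exp(eta))

    def B(self, eta):
        """Conditional mean ``A'(eta)``."""
        eta = np.asarray(eta, dtype=float)
        self._check_eta(eta)
        e = np.exp(eta)
        if self.name == "poisson":
            return e
        if self.name == "negbin":
            return self.r * e / (1.0 - e)
        return 1.0 / (1.0 - e)

    def B_prime(self, eta):
        """Conditional variance ``A''(eta)``."""
        eta = np.asarray(eta, dtype=float)
        self._check_eta(eta)
        e = np.exp(eta)
        if self.name == "poisson":
            return e
        if self.name == "negbin":
            return self.r * e / (1.0 - e) ** 2
        return e / (1.0 - e) ** 2

    def B_second(self, eta):
        """Third derivative of ``A`` (needed for loss Hessians)."""
        eta = np.asarray(eta, dtype=float)
        self._check_eta(eta)
        e = np.exp(eta)
        if self.name == "poisson":
            return e
        if self.name == "negbin":
            return self.r * e * (1.0 + e) / (1.0 - e) ** 3
        return e * (1.0 + e) / (1.0 - e) ** 3

    def B_inv(self, x):
        """Natural parameter for a given conditional mean."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= self.mean_floor):
            raise ValueError(
                f"mean must exceed {self.mean_floor} for family {self.name}"
            )
        if self.name == "poisson":
            return np.log(x)
        if self.name == "negbin":
            return np.log(x / (x + self.r))
        return np.log1p(-1.0 / x)

    def log_h(self, y):
        y = np.asarray(y, dtype=float)
        if self.name == "poisson":
            return -special.gammaln(y + 1.0)
        if self.name == "negbin":
            r = float(self.r)
            return (
                special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
            )
        return np.zeros_like(y)

    def log_pmf(self, y, eta):
        y = np.asarray(y)
        eta = np.asarray(eta, dtype=float)
        out = eta * y - self.A(eta) + self.log_h(y)
        below = np.asarray(y) < self.support_min
        if np.any(below):
            out = np.where(below, -np.inf, out)
        return out

    def sample(self, rng: np.random.Generator, mean):
        """Draw one count per mean value.

        Means at or below the support floor produce the degenerate draw at the
        floor (e.g. Poisson(0) = 0), matching an intensity recursion started
        at ``X_1 = 0``.
        """
        mean = np.asarray(mean, dtype=float)
        if self.name == "poisson":
            return rng.poisson(mean)
        if self.name == "negbin":
            m = np.maximum(mean, 0.0)
            out = np.where(
                m <= 0, 0, rng.negative_binomial(self.r, self.r / (self.r + np.maximum(m, 1e-300)))
            )
            return out
        m = np.maximum(mean, 1.0)
        return rng.geometric(1.0 / m)

    def truncation_ymax(self, mean_max: float, tol: float) -> int:
        """Upper summation limit so that the omitted tail mass is < ``tol``.

        Capped at ``mean + 50*sd + 100``; exponential tails make the inverse
        survival function far smaller than the cap in practice.
        """
        mean_max = float(mean_max)
        if self.name == "poisson":
            ymax = stats.poisson.isf(tol * 1e-2, mean_max)
            var = mean_max
        elif self.name == "negbin":
            p = self.r / (self.r + mean_max)
            ymax = stats.nbinom.isf(tol * 1e-2, self.r, p)
            var = mean_max * (mean_max + self.r) / self.r
        else:
            p = 1.0 / mean_max
            ymax = stats.geom.isf(tol * 1e-2, p)
            var = (1.0 - p) / p**2
        cap = mean_max + 50.0 * np.sqrt(var) + 100.0
        if not np.isfinite(ymax) or ymax > cap:
            raise ValueError("pmf truncation cap exceeded; check parameters")
        return int(ymax) + 5


POISSON = FamilySpec("poisson")
GEOMETRIC = FamilySpec("geometric_trials")


def negbin(r: int) -> FamilySpec:
    """Negative-binomial family with known size ``r``."""
    return FamilySpec("negbin", r=int(r))


# ---------------------------------------------------------------------------
# module-level operations


def natural_param(x, family: FamilySpec):
    """Map a conditional mean to the family's natural parameter ``B^{-1}(x)``."""
    return family.B_inv(x)


def log_pmf(y, eta, family: FamilySpec):
    return family.log_pmf(y, eta)


def pmf(y, eta, family: FamilySpec):
    """Probability mass ``p(y | eta)``; zero below the support floor."""
    with np.errstate(invalid="ignore"):
        out = np.exp(family.log_pmf(y, eta))
    return out


def mean_var(eta, family: FamilySpec):
    """Conditional mean and variance ``(B(eta), B'(eta))``."""
    return family.B(eta), family.B_prime(eta)


# ---------------------------------------------------------------------------
# intensity models


@dataclass(frozen=True)
class ModelSpec:
    """An INGARCH(1,1) or threshold INTGARCH(1,1) intensity recursion.

    ``bounds`` follow the compact-parameter-space shape required for the
    asymptotics: ``d in [d_low, d_high]`` and ``a + max(b's) <= 1 - eps``.
    Defaults are wide; they are a numerical guard, not a modelling choice.
    """

    family: FamilySpec
    form: str = "ingarch11"
    threshold_l: int = 0
    d_low: float = 1e-4
    d_high: float = 1e4
    eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.form not in ("ingarch11", "intgarch11"):
            raise ValueError(f"unknown model form {self.form!r}")
        if self.form == "intgarch11" and self.threshold_l < 0:
            raise ValueError("threshold_l must be a non-negative integer")
        if not (0 < self.d_low < self.d_high):
            raise ValueError("need 0 < d_low < d_high")
        if not 0 < self.eps < 1:
            raise ValueError("need 0 < eps < 1")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.form == "ingarch11":
            return ("d", "a", "b")
        return ("d", "a", "b1", "b2")

    @property
    def dim(self) -> int:
        return len(self.param_names)

    @property
    def box_bounds(self) -> list[tuple[float, float]]:
        hi = 1.0 - self.eps
        return [(self.d_low, self.d_high)] + [(0.0, hi)] * (self.dim - 1)

    def feasible(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            return False
        d, a = theta[0], theta[1]
        if not (self.d_low <= d <= self.d_high) or a < 0:
            return False
        if np.any(theta[2:] < 0):
            return False
        return a + float(np.max(theta[2:])) <= 1.0 - self.eps + 1e-12

    def check_theta(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if not self.feasible(theta):
            raise ValueError(f"theta {theta} outside the {self.form} parameter region")
        return theta

    def regressors(self, y) -> np.ndarray:
        """Lagged-count regressors entering the recursion with slopes b."""
        y = np.asarray(y, dtype=float)
        if self.form == "ingarch11":
            return y[:, None]
        l = float(self.threshold_l)
        return np.column_stack([np.maximum(y - l, 0.0), np.minimum(y, l)])

    def check_support(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("y must be a non-empty 1-d count series")
        if not np.issubdtype(y.dtype, np.integer):
            yi = np.asarray(y, dtype=float)
            if np.any(yi != np.round(yi)):
                raise ValueError("counts must be integers")
            y = yi.astype(np.int64)
        if np.any(y < self.family.support_min):
            raise ValueError(
                f"counts below the support floor {self.family.support_min} "
                f"of family {self.family.name}"
            )
        return np.asarray(y, dtype=np.int64)


@dataclass
class FilterState:
    """Intensity recursion output: ``X~_t`` and its theta-derivatives."""

    x_tilde: np.ndarray
    x_init: float
    grad: np.ndarray | None = None
    hess: np.ndarray | None = None


def _ar1_filter(u: np.ndarray, a: float, init: float = 0.0) -> np.ndarray:
    """Evaluate ``z_t = u_t + a * z_{t-1}`` with ``z_0 = init`` (vectorised)."""
    if abs(a) < 1e-300:
        return np.asarray(u, dtype=float).copy()
    out, _ = signal.lfilter([1.0], [1.0, -a], np.asarray(u, dtype=float),
                            zi=np.array([a * init]))
    return out


def intensity_filter(y, theta, model: ModelSpec, x_init: float) -> FilterState:
    """Run the intensity recursion ``X~_t(theta)`` from ``X~_1 = x_init``."""
    theta = model.check_theta(theta)
    y = model.check_support(y)
    x_init = float(x_init)
    if x_init < 0:
        raise ValueError("x_init must be non-negative")
    n = y.size
    if n == 1:
        return FilterState(np.array([x_init]), x_init)
    d, a = theta[0], theta[1]
    u = d + model.regressors(y[:-1]) @ theta[2:]
    x_rest = _ar1_filter(u, a, x_init)
    x = np.concatenate([[x_init], x_rest])
    if not np.all(np.isfinite(x)) or np.any(x[1:] <= 0):
        raise AssertionError("intensity recursion left the positive region")
    return FilterState(x, x_init)


def intensity_derivatives(y, theta, model: ModelSpec, x_init: float) -> FilterState:
    """Filter plus analytic first/second derivative recursions.

    The initial value is treated as free of ``theta`` (``g_1 = H_1 = 0``);
    initialization effects vanish geometrically and this keeps the filter a
    pure function of the data.
    """
    state = intensity_filter(y, theta, model, x_init)
    y = model.check_support(y)
    n = y.size
    p = model.dim
    a = float(theta[1])
    grad = np.zeros((n, p))
    hess = np.zeros((n, p, p))
    if n > 1:
        base = np.empty((n - 1, p))
        base[:, 0] = 1.0
        base[:, 1] = state.x_tilde[:-1]
        base[:, 2:] = model.regressors(y[:-1])
        for j in range(p):
            grad[1:, j] = _ar1_filter(base[:, j], a)
        # H_t = a H_{t-1} + e_a g_{t-1}^T + g_{t-1} e_a^T  (e_a = unit vec at a)
        for j in range(p):
            inp = grad[:-1, j].copy()
            if j == 1:
                inp *= 2.0
            col = _ar1_filter(inp, a)
            hess[1:, 1, j] = col
            hess[1:, j, 1] = col
    state.grad = grad
    state.hess = hess
    return state
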