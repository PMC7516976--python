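"""Reading count series and writing results, manifests and fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .families import GEOMETRIC, POISSON, FamilySpec, ModelSpec, negbin
from .simulate import ContaminationSpec, contaminate, simulate_ingarch

__all__ = [
    "read_count_series",
    "read_real_series",
    "family_from_name",
    "model_from_options",
    "write_json",
    "make_fixtures",
]


class DataError(ValueError):
    """Malformed input data (distinct from usage errors for exit codes)."""


def _read_single_column(path) -> tuple[np.ndarray, int]:
    """Parse a one-column CSV/TSV; returns values and the 1-based line offset
    of the first data row (for error messages)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    values, start = [], 1
    if not lines:
        raise DataError(f"{path}: empty file")
    first = lines[0].strip().split(",")[0].split("\t")[0]
    try:
        float(first)
    except ValueError:
        start = 2
        lines = lines[1:]
    for i, line in enumerate(lines, start=start):
        tok = line.strip()
        if not tok:
            continue
        tok = tok.split(",")[0].split("\t")[0]
        try:
            values.append(float(tok))
        except ValueError:
            raise DataError(f"{path}:{i}: not a number: {tok!r}") from None
    if not values:
        raise DataError(f"{path}: no data rows")
    return np.asarray(values), start


def read_count_series(path, family: FamilySpec | None = None) -> np.ndarray:
    """Load a single-column series of non-negative integer counts.

    An optional header line is skipped.  Non-integer or negative entries are
    rejected with the offending line number; if a family is given, the
    support floor is enforced as well.
    """
    vals, start = _read_single_column(path)
    for i, v in enumerate(vals):
        if v != np.round(v):
            raise DataError(f"{path}:{i + start}: non-integer count {v!r}")
        if v < 0:
            raise DataError(f"{path}:{i + start}: negative count {v!r}")
    y = vals.astype(np.int64)
    if family is not None and np.any(y < family.support_min):
        bad = int(np.argmax(y < family.support_min))
        raise DataError(
            f"{path}:{bad + start}: count below the support floor "
            f"{family.support_min} of family {family.name}"
        )
    return y


def read_real_series(path) -> np.ndarray:
    """Load a single-column real-valued series (e.g. log-returns)."""
    vals, _ = _read_single_column(path)
    return vals


def family_from_name(name: str, r: int = 10) -> FamilySpec:
    name = name.lower()
    if name == "poisson":
        return POISSON
    if name in ("geometric", "geometric_trials"):
        return GEOMETRIC
    if name in ("negbin", "nb", "negative_binomial"):
        return negbin(r)
    raise ValueError(f"unknown family {name!r}")


def model_from_options(family: str, r: int = 10, form: str = "ingarch11",
                       threshold_l: int = 0, d_low: float = 1e-4,
                       d_high: float = 1e4, eps: float = 1e-3) -> ModelSpec:
    return ModelSpec(family_from_name(family, r), form=form,
                     threshold_l=threshold_l, d_low=d_low, d_high=d_high,
                     eps=eps)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a deterministic bundle of small synthetic datasets.

    Clean Poisson / NB / geometric INGARCH series (n=500), contaminated
    twins of the Poisson and NB series, one mid-change Poisson series, and
    a synthetic heavy-tailed "log-return-like" series for the return-times
    constructor; a manifest records the generating parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 500
    manifest: dict = {"seed": seed, "n": n, "files": {}}

    def save(name, series, **meta):
        p = out / name
        pd.Series(series, name="value").to_csv(p, index=False)
        manifest["files"][name] = meta

    theta = (1.0, 0.2, 0.2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    models = {
        "poisson": ModelSpec(POISSON),
        "negbin": ModelSpec(negbin(10)),
        "geometric": ModelSpec(GEOMETRIC),
    }
    theta_by_family = {"poisson": theta, "negbin": theta,
                       "geometric": (1.5, 0.2, 0.2)}
    clean = {}
    for name, model in models.items():
        th = theta_by_family[name]
        y, _ = simulate_ingarch(model, th, n, seed=rng,
                                x1=model.family.mean_floor)
        clean[name] = y
        save(f"{name}_clean.csv", y, family=name, theta=list(th),
             kind="clean")

    cpois = ContaminationSpec(p=0.03, outlier_family="poisson", gamma=10.0)
    save("poisson_contaminated.csv", contaminate(clean["poisson"], cpois, rng),
         family="poisson", theta=list(theta), kind="contaminated",
         p=cpois.p, gamma=cpois.gamma)
    cnb = ContaminationSpec(p=0.03, outlier_family="negbin", r=10, kappa=0.5)
    save("negbin_contaminated.csv", contaminate(clean["negbin"], cnb, rng),
         family="negbin", theta=list(theta), kind="contaminated",
         p=cnb.p, r=cnb.r, kappa=cnb.kappa)

    y_change, _ = simulate_ingarch(models["poisson"], theta, n, seed=rng,
                                   theta1=(1.0, 0.2, 0.4))
    save("poisson_midchange.csv", y_change, family="poisson",
         theta=list(theta), theta1=[1.0, 0.2, 0.4], change_index=n // 2,
         kind="change")

    # heavy-tailed pseudo log-returns (Student t) for the return-times demo
    returns = rng.standard_t(df=3, size=3000) * 0.02
    save("synthetic_logreturns.csv", returns, kind="real_series",
         note="synthetic Student-t(3) pseudo log-returns")

    write_json(manifest, out / "manifest.json")
    return manifest
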