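"""Variable transformation and scaling grid applied before PCA / PLS-DA.

Three transformations (none, log10(C1*x + C2), (C1*x + C2)^C3) crossed with
four centering/scaling choices (none, center, center+UV, center+Pareto) on
each of the two schemas (individual metabolites and aglycone sums) give the
24-model pre-treatment grid.  Unit-variance (UV) scaling divides a centered
column by its standard deviation, Pareto by the square root of the standard
deviation.  Standard deviations use the n-1 divisor throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log10", "power")
SCALINGS = ("none", "center", "center+UV", "center+Pareto")
DATASETS = ("individual", "sums")


@dataclass(frozen=True)
class PretreatmentSpec:
    """One cell of the pre-treatment grid.

    Defaults follow the conventional constants: log10(1*x + 0) and
    (1*x + 0)^2.
    """

    transform: str = "none"
    c1: float = 1.0
    c2: float = 0.0
    c3: float = 2.0
    scaling: str = "none"
    dataset: str = "individual"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.c1 == 0:
            raise ValueError("C1 must be non-zero")

    def to_dict(self) -> dict:
        return asdict(self)


def transform(values: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    """Apply the spec's variable transformation elementwise.

    Non-positive arguments of the logarithm become missing (NaN) rather than
    errors: near-zero excretion values are a real feature of these data and
    the resulting missingness is carried through the missing-tolerant PCA.
    Missing cells stay missing.
    """
    x = np.asarray(values, dtype=float)
    if spec.transform == "none":
        return x.copy()
    arg = spec.c1 * x + spec.c2
    if spec.transform == "log10":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(arg > 0, np.log10(np.where(arg > 0, arg, 1.0)), np.nan)
        out = np.where(np.isnan(x), np.nan, out)
        n_new = int(np.isnan(out).sum() - np.isnan(x).sum())
        if n_new:
            logger.info("log10 transform created %d missing cell(s)", n_new)
        return out
    if spec.transform == "power":
        return arg**spec.c3
    raise AssertionError(spec.transform)


@dataclass
class ColumnStats:
    """Per-column centering/scaling constants, for back-transformation."""

    mean: np.ndarray
    divisor: np.ndarray
    zero_variance: np.ndarray  # flags: centered but not divided


def scale(values: np.ndarray, spec: PretreatmentSpec) -> tuple[np.ndarray, ColumnStats]:
    """Center/scale columns per the spec, ignoring missing cells.

    Returns the scaled matrix and the column statistics used, which allow
    exact back-transformation of complete columns.  Zero-variance columns
    are centered but not divided (flagged).  An all-missing column is an
    error.
    """
    x = np.asarray(values, dtype=float)
    n_obs = (~np.isnan(x)).sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("all-missing column(s) cannot be scaled")
    if spec.scaling != "none" and np.any(n_obs < 2):
        raise ValueError("scaling with centering needs >= 2 non-missing entries per column")
    if spec.scaling == "none":
        p = x.shape[1]
        stats = ColumnStats(np.zeros(p), np.ones(p), np.zeros(p, dtype=bool))
        return x.copy(), stats
    mean = np.nanmean(x, axis=0)
    centered = x - mean
    if spec.scaling == "center":
        p = x.shape[1]
        return centered, ColumnStats(mean, np.ones(p), np.zeros(p, dtype=bool))
    sd = np.nanstd(x, axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var):
        logger.warning("%d zero-variance column(s) centered but not divided", zero_var.sum())
    base = np.where(zero_var, 1.0, sd)
    divisor = base if spec.scaling == "center+UV" else np.sqrt(base)
    return centered / divisor, ColumnStats(mean, divisor, zero_var)


def pretreat(values: np.ndarray, spec: PretreatmentSpec) -> tuple[np.ndarray, ColumnStats]:
    """Transform then scale; the composite pipeline used by the PCA grid."""
    return scale(transform(values, spec), spec)


def enumerate_grid(datasets: tuple[str, ...] = DATASETS) -> list[PretreatmentSpec]:
    """Enumerate the pre-treatment grid in deterministic order.

    Dataset-major, then transform, then scaling: 3 x 4 cells per dataset,
    24 specs for both schemas.
    """
    return [
        PretreatmentSpec(transform=t, scaling=s, dataset=d)
        for d in datasets
        for t in TRANSFORMS
        for s in SCALINGS
    ]
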