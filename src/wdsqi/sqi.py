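"""Soil quality indices, fertility classification, and MDS validation.

Two composite indices are computed from membership scores:

* the weighted additive index ``WDSQI = sum_i W_i S_i`` (a convex combination,
  so it stays within the membership range [0.1, 1.0]);
* the improved Nemerow index
  ``WDSQIN = sqrt((fbar^2 + fmin^2) / 2) * (n - 1) / n``,
  which mixes the mean membership with the *minimum* membership, implementing
  the "barrel theory" that overall fertility is capped by the most deficient
  indicator. The (n - 1)/n factor discounts small panels, so the index lives
  in [0.1 (n-1)/n, (n-1)/n].

Composite values map onto five fertility classes split at 0.4 / 0.6 / 0.7 /
0.8 (boundaries belong to the lower class; only values strictly above 0.8 are
Excellent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .model import MembershipTable
from .weighting import WeightVector

CLASSES = ("Destitute", "Deficient", "Medium", "Good", "Excellent")
DEFAULT_BOUNDS = (0.4, 0.6, 0.7, 0.8)

CV_BANDS = (
    (10.0, "Insensitive"),
    (50.0, "Low"),
    (100.0, "Moderate"),
    (np.inf, "Strong"),
)


def classify(index: float, bounds=DEFAULT_BOUNDS) -> str:
    """Fertility class of a composite index value (boundaries round down)."""
    x = float(index)
    if not np.isfinite(x):
        raise ValidationError("index value must be finite")
    for b, label in zip(bounds, CLASSES):
        if x <= b:
            return label
    return CLASSES[-1]


@dataclass(frozen=True)
class SQIResult:
    """Per-sample and per-plot values of one composite index."""

    method: str
    per_sample: pd.Series
    per_plot: pd.Series
    classes: pd.Series  # fertility class per plot

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index_value": self.per_plot, "fertility_class": self.classes}
        ).rename_axis("plot_id")


def _per_plot(per_sample: pd.Series, bounds) -> tuple[pd.Series, pd.Series]:
    per_plot = per_sample.groupby(level="plot_id", sort=False).mean()
    classes = per_plot.map(lambda v: classify(v, bounds))
    return per_plot, classes


def wdsqi_weighted_additive(
    memberships: MembershipTable,
    weights: WeightVector,
    bounds=DEFAULT_BOUNDS,
) -> SQIResult:
    """Weighted additive index per sample; plot value is the sample mean.

    The weight vector may cover a subset of the membership columns (the MDS
    case); weights must sum to one.
    """
    missing = [i for i in weights.indicators if i not in memberships.indicators]
    if missing:
        raise ConfigurationError(f"weights refer to unknown indicators {missing}")
    cols = weights.indicators
    vals = memberships.data[cols].to_numpy() @ weights.weight.to_numpy()
    per_sample = pd.Series(vals, index=memberships.data.index, name="wdsqi")
    per_plot, classes = _per_plot(per_sample, bounds)
    return SQIResult(
        method=f"weighted_additive_{weights.label}",
        per_sample=per_sample,
        per_plot=per_plot,
        classes=classes,
    )


def nemerow_improved(memberships) -> float:
    """Improved Nemerow index of one membership vector."""
    f = np.asarray(memberships, dtype=float)
    if f.size == 0:
        raise ValidationError("empty membership vector")
    n = f.size
    if n < 2:
        raise ValidationError("need at least 2 indicators")
    return float(np.sqrt((f.mean() ** 2 + f.min() ** 2) / 2.0) * (n - 1) / n)


def nemerow_table(
    memberships: MembershipTable,
    aggregate: str = "per_sample",
    bounds=DEFAULT_BOUNDS,
) -> SQIResult:
    """Improved Nemerow index for every sample.

    ``aggregate='per_sample'`` (default) averages per-sample index values
    within each plot; ``aggregate='plot_mean'`` instead applies the formula
    once to each plot's mean membership profile.
    """
    per_sample = pd.Series(
        [nemerow_improved(row) for row in memberships.data.to_numpy()],
        index=memberships.data.index,
        name="wdsqin",
    )
    if aggregate == "per_sample":
        per_plot, classes = _per_plot(per_sample, bounds)
    elif aggregate == "plot_mean":
        pm = memberships.data.groupby(level="plot_id", sort=False).mean()
        per_plot = pd.Series(
            [nemerow_improved(row) for row in pm.to_numpy()], index=pm.index
        )
        classes = per_plot.map(lambda v: classify(v, bounds))
    else:
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    return SQIResult(
        method="nemerow_improved",
        per_sample=per_sample,
        per_plot=per_plot,
        classes=classes,
    )


def nemerow_legacy(values, variant: str = "eq4_min", literal: bool = False) -> float:
    """Classical Nemerow forms kept for auditability.

    ``eq4_min`` is the minimum-based form with the (n-1)/n correction and is
    definitionally identical to :func:`nemerow_improved`. ``eq3_max`` is the
    historical maximum-based form ``sqrt((mean^2 + max^2)/2)`` without the
    correction; ``literal=True`` evaluates the asymmetric variant
    ``sqrt(mean + max^2/2)`` that some sources print (almost certainly a
    typesetting slip — the mean enters unsquared).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty value vector")
    if variant == "eq4_min":
        return nemerow_improved(v)
    if variant != "eq3_max":
        raise ConfigurationError(f"unknown variant {variant!r}")
    if literal:
        return float(np.sqrt(v.mean() + v.max() ** 2 / 2.0))
    return float(np.sqrt((v.mean() ** 2 + v.max() ** 2) / 2.0))


def cv_sensitivity(values) -> tuple[float, str]:
    """Coefficient of variation (percent, n-1 sd) and its sensitivity band.

    Bands: < 10% insensitive, 10-50% low, 50-100% moderate, >= 100% strong.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise DegenerateInputError("CV undefined for zero mean")
    cv = 100.0 * v.std(ddof=1) / abs(mean)
    for upper, label in CV_BANDS:
        if cv < upper:
            return float(cv), label
    return float(cv), "Strong"


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def validate_mds_vs_tds(tds_sqi, mds_sqi) -> RegressionFit:
    """OLS fit of the MDS index on the TDS index across samples.

    A high R^2 indicates the reduced indicator set preserves the quality
    signal of the full panel.
    """
    x = np.asarray(tds_sqi, dtype=float)
    y = np.asarray(mds_sqi, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need two equal-length vectors with >= 3 samples")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the TDS index")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
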