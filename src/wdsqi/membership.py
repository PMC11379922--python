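"""Fuzzy membership scoring of soil indicators.

Measured values are mapped onto a dimensionless score in [0.1, 1.0] by one of
two piecewise-linear families:

* **S-type** (monotone rising, used for the nutrient stocks SOM, AN, AP, AK,
  TP, TN): the score is 0.1 below the lower breakpoint ``m1``, rises linearly
  as ``0.9 (x - m1)/(m2 - m1) + 0.1``, and saturates at 1.0 from ``m2`` up.
* **Parabolic** (optimum plateau, used for pH, SMC, BD): 0.1 outside
  ``(x1, x4)``, a rising ramp on ``[x1, x2)``, a plateau at 1.0 on
  ``[x2, x3)``, and a falling ramp ``0.9 (x4 - x)/(x4 - x3) + 0.1`` on
  ``[x3, x4)``.

The floor of 0.1 (rather than 0) keeps every indicator with a nonzero
contribution in downstream composite indices. Endpoint conventions: exactly
``x2`` scores 1.0 (continuity of the rising ramp) and exactly ``x4`` scores
0.1 (limit of the falling ramp); values above ``x4`` score 0.1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, ValidationError
from .model import PARABOLIC, S_TYPE, IndicatorSpec, MembershipTable, SampleTable


def score_s_type(value, m1: float, m2: float):
    """Monotone rising score. Accepts a scalar or array, returns the same shape."""
    if not m1 < m2:
        raise ParameterError(f"require m1 < m2, got ({m1}, {m2})")
    x = np.asarray(value, dtype=float)
    out = np.where(
        x >= m2, 1.0, np.where(x < m1, 0.1, 0.9 * (x - m1) / (m2 - m1) + 0.1)
    )
    return out.item() if np.isscalar(value) or out.ndim == 0 else out


def score_parabolic(value, x1: float, x2: float, x3: float, x4: float):
    """Optimum-plateau score. Accepts a scalar or array, returns the same shape."""
    if not (x1 < x2 <= x3 < x4):
        raise ParameterError(f"require x1 < x2 <= x3 < x4, got ({x1}, {x2}, {x3}, {x4})")
    x = np.asarray(value, dtype=float)
    out = np.full(x.shape, 0.1)
    rising = (x >= x1) & (x < x2)
    plateau = (x >= x2) & (x < x3)
    falling = (x >= x3) & (x < x4)
    out[rising] = 0.9 * (x[rising] - x1) / (x2 - x1) + 0.1
    out[plateau] = 1.0
    out[falling] = 0.9 * (x4 - x[falling]) / (x4 - x3) + 0.1
    return out.item() if np.isscalar(value) or out.ndim == 0 else out


def score_value(value, spec: IndicatorSpec):
    """Score one value (or array) under an indicator's spec."""
    if spec.fn_kind == S_TYPE:
        return score_s_type(value, *spec.params)
    if spec.fn_kind == PARABOLIC:
        return score_parabolic(value, *spec.params)
    raise ConfigurationError(f"unknown function kind {spec.fn_kind!r}")


def score_table(samples: SampleTable, specs: Sequence[IndicatorSpec]) -> MembershipTable:
    """Apply each indicator's membership function elementwise.

    Every column of ``samples`` must have a matching spec; extra specs are
    ignored.
    """
    by_name = {s.name: s for s in specs}
    missing = [c for c in samples.indicators if c not in by_name]
    if missing:
        raise ConfigurationError(f"no membership spec for indicators {missing}")
    scored = {
        col: np.atleast_1d(score_value(samples.data[col].to_numpy(), by_name[col]))
        for col in samples.indicators
    }
    return MembershipTable(pd.DataFrame(scored, index=samples.data.index))


def plot_mean_membership(memberships: MembershipTable) -> pd.DataFrame:
    """Arithmetic mean score per plot and indicator (plots x indicators)."""
    if len(memberships) == 0:
        raise ValidationError("empty membership table")
    means = memberships.data.groupby(level="plot_id", sort=False).mean()
    return means[memberships.indicators]
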