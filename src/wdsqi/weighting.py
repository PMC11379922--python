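"""Indicator weights from PCA communalities (common factor variances).

The communality of indicator *i* over the retained components,
``h2_i = sum_k U_ik^2``, measures how much of that indicator's variance the
retained components explain — its contribution to the common structure.
Weights are communalities normalized to sum to one. Weights are derived
separately for the full indicator panel (TDS) and for the selected subset
(MDS, via a fresh PCA on only those indicators).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mds import PCAResult, pca_correlation, retain_components, standardize
from .model import Config, SampleTable


def communalities(pca: PCAResult, retained: Sequence[int]) -> pd.Series:
    """``sum_{k in retained} U_ik^2`` per indicator."""
    if not retained:
        raise ValidationError("no retained components")
    cols = [f"PC{k}" for k in retained]
    return (pca.loadings[cols] ** 2).sum(axis=1).rename("communality")


@dataclass(frozen=True)
class WeightVector:
    """Per-indicator communality and normalized weight for one indicator set."""

    communality: pd.Series
    weight: pd.Series
    label: str = "TDS"

    def __post_init__(self) -> None:
        if abs(float(self.weight.sum()) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")

    @property
    def indicators(self) -> list[str]:
        return list(self.weight.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"communality": self.communality, "weight": self.weight}
        ).rename_axis("indicator")


def weights_from_communalities(comm: pd.Series, label: str = "TDS") -> WeightVector:
    """Normalize positive communalities into weights summing to one."""
    comm = pd.Series(comm, dtype=float)
    if (comm <= 0).any():
        bad = comm.index[comm <= 0][0]
        raise ValidationError(f"non-positive communality for {bad!r}")
    w = comm / comm.sum()
    return WeightVector(communality=comm, weight=w.rename("weight"), label=label)


def weights_from_samples(
    samples: SampleTable,
    indicators: Sequence[str] | None = None,
    config: Config | None = None,
    label: str = "TDS",
) -> WeightVector:
    """PCA-communality weights computed from raw samples.

    ``indicators`` restricts the panel (e.g. to the selected MDS); the PCA and
    the eigenvalue/variance retention rule are applied to that panel alone.
    """
    cfg = config or Config()
    if indicators is not None:
        sub = SampleTable(samples.data[list(indicators)])
    else:
        sub = samples
    z = standardize(sub)
    pca = pca_correlation(z)
    retained = retain_components(pca, cfg.eigen_floor, cfg.variance_floor)
    return weights_from_communalities(communalities(pca, retained), label=label)
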