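"""Domain types: indicator specifications, sample tables, plot summaries, config.

The nine physicochemical indicators of the total data set (TDS) are kept in a
fixed canonical order everywhere so that every derived table (memberships,
loadings, weights) is deterministic regardless of input column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError, ValidationError

#: Canonical indicator order used for all outputs.
INDICATORS: tuple[str, ...] = ("pH", "SOM", "AN", "AP", "AK", "TP", "TN", "SMC", "BD")

S_TYPE = "s_type"
PARABOLIC = "parabolic"

KEY_COLUMNS = ("plot_id", "sample_id")


@dataclass(frozen=True)
class IndicatorSpec:
    """Identity and membership-function parameters of one soil indicator.

    ``params`` is ``(m1, m2)`` for the monotone S-type function and
    ``(x1, x2, x3, x4)`` for the parabolic (optimum-plateau) function, in the
    indicator's own measurement units. Units are metadata only; they never
    enter any computation.
    """

    name: str
    units: str
    fn_kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.fn_kind not in (S_TYPE, PARABOLIC):
            raise ParameterError(f"unknown membership function kind {self.fn_kind!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.fn_kind == S_TYPE:
            if len(p) != 2:
                raise ParameterError(f"{self.name}: s_type needs (m1, m2), got {p}")
            if not p[0] < p[1]:
                raise ParameterError(f"{self.name}: require m1 < m2, got {p}")
        else:
            if len(p) != 4:
                raise ParameterError(f"{self.name}: parabolic needs (x1..x4), got {p}")
            x1, x2, x3, x4 = p
            if not (x1 < x2 <= x3 < x4):
                raise ParameterError(
                    f"{self.name}: require x1 < x2 <= x3 < x4, got {p}"
                )


def spec_order(specs: Sequence[IndicatorSpec]) -> list[str]:
    """Names of ``specs`` sorted into the canonical indicator order.

    Unknown names (custom indicators) keep their given relative order after
    the canonical ones.
    """
    names = [s.name for s in specs]
    known = [n for n in INDICATORS if n in names]
    extra = [n for n in names if n not in INDICATORS]
    return known + extra


def _validate_values(df: pd.DataFrame, lo: float, hi: float, what: str) -> None:
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = df.columns[np.argwhere(~np.isfinite(arr))[0][1]]
        raise ValidationError(f"{what}: non-finite value in column {bad!r}")
    if (arr < lo).any() or (arr > hi).any():
        bad = df.columns[np.argwhere((arr < lo) | (arr > hi))[0][1]]
        raise ValidationError(
            f"{what}: value outside [{lo}, {hi}] in column {bad!r}"
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample measured indicator values for one or more plots.

    ``data`` is indexed by a (plot_id, sample_id) MultiIndex with one float
    column per indicator, in canonical order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.MultiIndex) or tuple(df.index.names) != KEY_COLUMNS:
            raise ValidationError("SampleTable index must be (plot_id, sample_id)")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate (plot_id, sample_id) key {dup!r}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = df.columns[np.argwhere(~np.isfinite(arr))[0][1]]
            raise ValidationError(f"non-finite value in column {bad!r}")
        for col in df.columns:
            v = df[col].to_numpy(dtype=float)
            if col == "pH":
                if ((v <= 0) | (v >= 14)).any():
                    raise ValidationError("pH values must lie in (0, 14)")
            elif (v < 0).any():
                raise ValidationError(f"negative value in column {col!r}")
        object.__setattr__(self, "data", df.astype(float))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, indicators: Sequence[str] | None = None) -> "SampleTable":
        """Build from a flat frame with plot_id / sample_id columns."""
        from .errors import SchemaError

        cols = indicators if indicators is not None else [
            c for c in frame.columns if c not in KEY_COLUMNS
        ]
        for key in KEY_COLUMNS:
            if key not in frame.columns:
                raise SchemaError(f"missing required column {key!r}")
        for col in cols:
            if col not in frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        ordered = [c for c in INDICATORS if c in cols] + [
            c for c in cols if c not in INDICATORS
        ]
        df = frame.set_index(list(KEY_COLUMNS))[ordered]
        return cls(df)

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns)

    @property
    def plots(self) -> list:
        return list(dict.fromkeys(self.data.index.get_level_values("plot_id")))

    def to_frame(self) -> pd.DataFrame:
        return self.data.reset_index()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class MembershipTable:
    """Per-sample membership scores on [0.1, 1.0], same keying as SampleTable."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.MultiIndex) or tuple(df.index.names) != KEY_COLUMNS:
            raise ValidationError("MembershipTable index must be (plot_id, sample_id)")
        _validate_values(df, 0.1 - 1e-12, 1.0 + 1e-12, "membership score")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns)

    @property
    def plots(self) -> list:
        return list(dict.fromkeys(self.data.index.get_level_values("plot_id")))

    def to_frame(self) -> pd.DataFrame:
        return self.data.reset_index()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class PlotSummary:
    """Per-plot mean and standard deviation of each indicator."""

    plot_id: str
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise ValidationError(f"{self.plot_id}: mean/sd indicator sets differ")
        if any(s < 0 for s in self.sds.values()):
            raise ValidationError(f"{self.plot_id}: negative standard deviation")


@dataclass(frozen=True)
class Config:
    """Tunable thresholds of the selection pipeline and classification bounds.

    Defaults encode the framework's stated rules: components are retained when
    their eigenvalue is >= 1 and they explain >= 5% of variance; an indicator
    belongs to a component when its |loading| >= 0.6; the per-group shortlist
    keeps indicators within 10% of the group's top |loading|; shortlisted
    indicators correlated at |r| > 0.5 are redundant; fertility classes split
    at (0.4, 0.6, 0.7, 0.8).
    """

    specs: tuple[IndicatorSpec, ...] = ()
    eigen_floor: float = 1.0
    variance_floor: float = 5.0  # percent
    loading_cutoff: float = 0.6
    shortlist_tol: float = 0.10
    redundancy_r: float = 0.5
    class_bounds: tuple[float, float, float, float] = (0.4, 0.6, 0.7, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.loading_cutoff <= 1:
            raise ConfigurationError("loading_cutoff must lie in (0, 1]")
        if not 0 < self.shortlist_tol < 1:
            raise ConfigurationError("shortlist_tol must lie in (0, 1)")
        if not 0 < self.redundancy_r <= 1:
            raise ConfigurationError("redundancy_r must lie in (0, 1]")
        if self.variance_floor < 0 or self.variance_floor > 100:
            raise ConfigurationError("variance_floor is a percentage")
        b = self.class_bounds
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ConfigurationError("class_bounds must be 4 strictly increasing values")

    def with_specs(self, specs: Iterable[IndicatorSpec]) -> "Config":
        return replace(self, specs=tuple(specs))

    @classmethod
    def default(cls) -> "Config":
        from .io import load_fixture

        return cls(specs=tuple(load_fixture("membership_params")))

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        specs = tuple(
            IndicatorSpec(
                name=s["name"],
                units=s.get("units", ""),
                fn_kind=s["fn_kind"],
                params=tuple(s["params"]),
            )
            for s in raw.pop("specs", [])
        )
        if "class_bounds" in raw:
            raw["class_bounds"] = tuple(raw["class_bounds"])
        cfg = cls(specs=specs, **raw)
        if not specs:
            cfg = cfg.with_specs(Config.default().specs)
        return cfg

    def to_yaml(self, path) -> None:
        payload = {
            "specs": [
                {
                    "name": s.name,
                    "units": s.units,
                    "fn_kind": s.fn_kind,
                    "params": list(s.params),
                }
                for s in self.specs
            ],
            "eigen_floor": self.eigen_floor,
            "variance_floor": self.variance_floor,
            "loading_cutoff": self.loading_cutoff,
            "shortlist_tol": self.shortlist_tol,
            "redundancy_r": self.redundancy_r,
            "class_bounds": list(self.class_bounds),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
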