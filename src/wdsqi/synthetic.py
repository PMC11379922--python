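"""Synthetic sample-table generator with the study's statistical structure.

Emulates the sampling design the analysis assumes: five waste-dump plots,
five samples each, nine indicators. Each plot draws from a multivariate
normal with that plot's published mean/SD vector and a correlation matrix
shared across plots (the published pooled matrix, repaired to the nearest
positive semidefinite correlation matrix). Draws outside physical bounds
(pH must lie in (0, 14), everything else must be positive) are rejected and
redrawn, so marginals are truncated normals without point masses at the
bounds.

Each plot gets its own deterministic substream derived from the master seed
and the plot id, so generated tables are reproducible and invariant to plot
ordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .model import INDICATORS, PlotSummary, SampleTable

_MAX_REJECT_BATCHES = 200


def default_bounds(indicators: Sequence[str]) -> dict[str, tuple[float, float]]:
    return {
        name: (0.0, 14.0) if name == "pH" else (0.0, np.inf) for name in indicators
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the published study design."""

    plots: tuple[PlotSummary, ...]
    correlation: pd.DataFrame
    n_per_plot: int = 5
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_plot < 1:
            raise ConfigurationError("n_per_plot must be >= 1")
        if not self.plots:
            raise ConfigurationError("at least one plot required")
        names = list(self.plots[0].means)
        for ps in self.plots:
            if list(ps.means) != names:
                raise ConfigurationError("all plots must share one indicator set")
        corr = self.correlation
        if list(corr.index) != names or list(corr.columns) != names:
            corr = corr.reindex(index=names, columns=names)
        arr = corr.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ConfigurationError("correlation matrix does not cover all indicators")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValidationError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(arr).min() < -1e-8:
            raise ConfigurationError(
                "correlation matrix is not positive semidefinite; "
                "run repair_correlation first"
            )
        object.__setattr__(self, "correlation", corr)
        if not self.bounds:
            object.__setattr__(self, "bounds", default_bounds(names))

    @property
    def indicators(self) -> list[str]:
        return list(self.plots[0].means)


def repair_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Nearest-PSD repair: clip negative eigenvalues, renormalize diagonal.

    PSD inputs pass through unchanged (to within 1e-12). Published matrices
    rounded to 2-3 decimals are often marginally indefinite; for such inputs
    the repair perturbs entries by well under 0.05.
    """
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh((arr + arr.T) / 2.0)
    if w.min() >= 0:
        out = arr
    else:
        fixed = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(fixed))
        out = fixed / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
        out = (out + out.T) / 2.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def default_config(seed: int = 0, n_per_plot: int = 5) -> SyntheticConfig:
    """Published plot statistics + repaired published correlation matrix."""
    from .io import load_fixture

    plots = tuple(load_fixture("plot_summaries"))
    corr = repair_correlation(load_fixture("correlations"))
    return SyntheticConfig(plots=plots, correlation=corr, n_per_plot=n_per_plot, seed=seed)


def _plot_rng(seed: int, plot_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(plot_id).encode())])
    )


def generate_samples(config: SyntheticConfig) -> SampleTable:
    """Draw a full SampleTable under ``config`` (bit-reproducible per seed)."""
    names = config.indicators
    corr = config.correlation.to_numpy(dtype=float)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    frames = []
    for ps in config.plots:
        mu = np.array([ps.means[n] for n in names])
        sd = np.array([ps.sds[n] for n in names])
        cov = corr * np.outer(sd, sd)
        rng = _plot_rng(config.seed, ps.plot_id)
        need = config.n_per_plot
        accepted: list[np.ndarray] = []
        drawn = 0
        for _ in range(_MAX_REJECT_BATCHES):
            batch = rng.multivariate_normal(mu, cov, size=max(need * 2, 16), method="svd")
            drawn += len(batch)
            ok = np.all((batch > lo) & (batch < hi), axis=1)
            accepted.extend(batch[ok])
            if len(accepted) >= need:
                break
        else:
            raise ConfigurationError(
                f"plot {ps.plot_id}: rejection rate above 99% "
                f"({len(accepted)}/{drawn} accepted); check means/SDs vs bounds"
            )
        rows = np.vstack(accepted[:need])
        idx = pd.MultiIndex.from_tuples(
            [(ps.plot_id, f"{ps.plot_id}-{j + 1}") for j in range(need)],
            names=("plot_id", "sample_id"),
        )
        frames.append(pd.DataFrame(rows, index=idx, columns=names))
    return SampleTable(pd.concat(frames))


@dataclass(frozen=True)
class RecoveryReport:
    """Summary of repeated end-to-end selection runs on synthetic studies."""

    replicates: int
    inclusion_freq: pd.Series  # fraction of replicates each indicator entered the MDS
    size_counts: dict[int, int]
    eigenvalue_mean: np.ndarray
    eigenvalue_sd: np.ndarray

    @property
    def most_selected(self) -> str:
        return self.inclusion_freq.idxmax()


def end_to_end_recovery(
    config: SyntheticConfig, replicates: int, seed: int
) -> RecoveryReport:
    """Run standardize -> PCA -> retain -> Norm -> group -> select on fresh
    synthetic studies and tabulate what gets selected."""
    from .mds import select_mds_from_samples

    if replicates < 10:
        raise ConfigurationError("need at least 10 replicates")
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=replicates)
    names = config.indicators
    counts = pd.Series(0.0, index=names)
    sizes: dict[int, int] = {}
    eigs = []
    for s in rep_seeds:
        samples = generate_samples(replace(config, seed=int(s)))
        sel, pca, _, _ = select_mds_from_samples(samples)
        for ind in sel.selected:
            counts[ind] += 1
        sizes[len(sel.selected)] = sizes.get(len(sel.selected), 0) + 1
        eigs.append(pca.eigenvalues)
    eigs_arr = np.vstack(eigs)
    return RecoveryReport(
        replicates=replicates,
        inclusion_freq=counts / replicates,
        size_counts=dict(sorted(sizes.items())),
        eigenvalue_mean=eigs_arr.mean(axis=0),
        eigenvalue_sd=eigs_arr.std(axis=0, ddof=1),
    )
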