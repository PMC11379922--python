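"""Minimum-data-set (MDS) selection via correlation-matrix PCA and Norm values.

The total data set (TDS) of nine indicators is reduced to a small,
low-redundancy subset in five steps:

1. standardize each indicator (mean 0, unit sample variance);
2. eigendecompose the Pearson correlation matrix; loadings are
   ``U_ik = v_ik * sqrt(lambda_k)``;
3. retain components with eigenvalue >= 1 that explain >= 5% of variance;
4. score each indicator by its *comprehensive load*
   ``CL_i = sum_k U_ik^2 * lambda_k`` over retained components (the "Norm"
   value is its square root — both rank indicators identically);
5. group indicators by component (|loading| >= 0.6; cross-loaders go to the
   group they are least correlated with), shortlist each group to indicators
   within 10% of its top |loading|, and break |r| > 0.5 redundancy in favour
   of the higher comprehensive load.

All loading rules use absolute values. Redundancy filtering operates within
group shortlists only; representatives of different components are never
tested against each other. Ties break by canonical indicator order, so the
selection (and its audit log) is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .model import Config, SampleTable

_EPS = 1e-10


def standardize(samples: SampleTable) -> pd.DataFrame:
    """Columnwise (x - mean) / sd with the n-1 denominator."""
    df = samples.data
    if len(df) < 3:
        raise DegenerateInputError("need at least 3 samples to standardize")
    sd = df.std(ddof=1)
    zero = sd[sd <= 0]
    if len(zero):
        raise DegenerateInputError(f"zero variance in indicator {zero.index[0]!r}")
    return (df - df.mean()) / sd


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of a correlation matrix, with loadings.

    ``eigenvalues`` are in descending order and sum to the number of
    indicators; ``loadings`` has indicators as rows and PC1..PCp as columns.
    Each component's sign is fixed so its largest-|loading| entry is positive.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame

    @property
    def indicators(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def n_indicators(self) -> int:
        return len(self.loadings)

    @property
    def variance_pct(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.n_indicators

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.variance_pct)

    @classmethod
    def from_loadings(
        cls, loadings: pd.DataFrame, eigenvalues: Sequence[float]
    ) -> "PCAResult":
        """Wrap an externally supplied loading matrix (e.g. a published table).

        Missing trailing eigenvalues are padded with zeros so variance
        fractions still use the full indicator count.
        """
        ev = np.asarray(eigenvalues, dtype=float)
        cols = [f"PC{k + 1}" for k in range(loadings.shape[1])]
        ld = loadings.copy()
        ld.columns = cols
        return cls(eigenvalues=ev, loadings=ld.astype(float))


def pca_correlation(data) -> PCAResult:
    """PCA of a correlation matrix.

    ``data`` may be a p x p symmetric correlation matrix (unit diagonal) or an
    n x p standardized data matrix (n >= p + 1), either as a DataFrame
    (indicator names taken from columns/index) or ndarray.
    """
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        names = list(data.columns)
    else:
        arr = np.asarray(data, dtype=float)
        names = [f"x{i + 1}" for i in range(arr.shape[1])]
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite values in PCA input")
    square = arr.shape[0] == arr.shape[1]
    if square and np.allclose(arr, arr.T, atol=1e-8) and np.allclose(
        np.diag(arr), 1.0, atol=1e-8
    ):
        corr = (arr + arr.T) / 2.0
    elif square:
        raise ValidationError(
            "square PCA input must be a symmetric correlation matrix with unit diagonal"
        )
    else:
        if arr.shape[0] < arr.shape[1] + 1:
            raise ValidationError("need at least p + 1 samples for PCA from data")
        corr = np.atleast_2d(np.corrcoef(arr, rowvar=False))
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Rounded published matrices can be marginally indefinite; loadings use
    # the non-negative part of each eigenvalue.
    load = evecs * np.sqrt(np.clip(evals, 0.0, None))
    for k in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, k])), k] < 0:
            load[:, k] = -load[:, k]
    cols = [f"PC{k + 1}" for k in range(load.shape[1])]
    return PCAResult(
        eigenvalues=evals, loadings=pd.DataFrame(load, index=names, columns=cols)
    )


def retain_components(
    pca: PCAResult, eigen_floor: float = 1.0, variance_floor: float = 5.0
) -> list[int]:
    """1-based component numbers with eigenvalue >= floor and variance share
    >= floor (percent). The leading component is always retained."""
    keep = [
        k + 1
        for k in range(len(pca.eigenvalues))
        if pca.eigenvalues[k] >= eigen_floor - _EPS
        and pca.variance_pct[k] >= variance_floor - _EPS
    ]
    if 1 not in keep:
        import logging

        logging.getLogger("wdsqi").warning(
            "leading component fails the retention rule; retaining it anyway"
        )
        keep = [1] + keep
    return keep


@dataclass(frozen=True)
class NormScores:
    """Comprehensive load and its square root per indicator.

    ``norm = sqrt(comprehensive_load)``; the two rank indicators identically,
    so MDS selection is invariant to which one is used.
    """

    table: pd.DataFrame  # columns: comprehensive_load, norm

    @property
    def comprehensive_load(self) -> pd.Series:
        return self.table["comprehensive_load"]

    @property
    def norm(self) -> pd.Series:
        return self.table["norm"]


def norm_scores(pca: PCAResult, retained: Sequence[int]) -> NormScores:
    """``CL_i = sum_{k in retained} U_ik^2 lambda_k`` and its square root."""
    if not retained:
        raise ValidationError("no retained components")
    cl = pd.Series(0.0, index=pca.loadings.index)
    for k in retained:
        cl = cl + pca.loadings[f"PC{k}"] ** 2 * pca.eigenvalues[k - 1]
    out = pd.DataFrame({"comprehensive_load": cl, "norm": np.sqrt(cl)})
    return NormScores(out)


def _canon_rank(names: Sequence[str]) -> dict:
    return {n: i for i, n in enumerate(names)}


def group_indicators(
    pca: PCAResult,
    retained: Sequence[int],
    correlations: pd.DataFrame,
    loading_cutoff: float = 0.6,
    audit: list | None = None,
) -> dict[str, int]:
    """Assign each indicator to one retained component.

    |loading| >= cutoff on exactly one component -> that component; on two or
    more -> the component whose already-assigned members have the smallest
    mean |r| with the indicator; below cutoff everywhere -> the component
    carrying its largest |loading|.
    """
    audit = audit if audit is not None else []
    absload = pca.loadings[[f"PC{k}" for k in retained]].abs()
    groups: dict[str, int] = {}
    cross: list[str] = []
    for ind in pca.indicators:
        hits = [k for k in retained if absload.loc[ind, f"PC{k}"] >= loading_cutoff]
        if len(hits) == 1:
            groups[ind] = hits[0]
            audit.append(f"{ind}: |loading| >= {loading_cutoff} on PC{hits[0]} only -> group PC{hits[0]}")
        elif len(hits) == 0:
            best = retained[int(np.argmax([absload.loc[ind, f"PC{k}"] for k in retained]))]
            groups[ind] = best
            audit.append(
                f"{ind}: below cutoff on all retained components -> "
                f"group of largest |loading| PC{best}"
            )
        else:
            cross.append(ind)
    for ind in cross:
        hits = [k for k in retained if absload.loc[ind, f"PC{k}"] >= loading_cutoff]
        mean_r = {}
        for k in hits:
            members = [m for m, g in groups.items() if g == k and m != ind]
            if members:
                mean_r[k] = float(np.mean([abs(correlations.loc[ind, m]) for m in members]))
        if mean_r:
            best = min(sorted(mean_r), key=lambda k: mean_r[k])
            audit.append(
                f"{ind}: cross-loads on {['PC%d' % k for k in hits]}; mean |r| with members "
                + ", ".join(f"PC{k}={mean_r[k]:.3f}" for k in sorted(mean_r))
                + f" -> group PC{best} (least correlated)"
            )
        else:
            best = hits[int(np.argmax([absload.loc[ind, f"PC{k}"] for k in hits]))]
            audit.append(f"{ind}: cross-loads but no assigned peers; largest |loading| -> PC{best}")
        groups[ind] = best
    return groups


@dataclass(frozen=True)
class MDSSelection:
    """Outcome of the selection procedure with a human-readable audit trail."""

    groups: dict[str, int]
    shortlists: dict[int, list[str]]
    selected: list[str]
    audit: list[str] = field(default_factory=list)


def select_mds(
    pca: PCAResult,
    correlations: pd.DataFrame,
    norms: NormScores,
    groups: dict[str, int],
    shortlist_tol: float = 0.10,
    redundancy_r: float = 0.5,
    audit: list | None = None,
) -> MDSSelection:
    """Shortlist each group and break redundancy; union of survivors = MDS."""
    audit = audit if audit is not None else []
    rank = _canon_rank(pca.indicators)
    shortlists: dict[int, list[str]] = {}
    selected: list[str] = []
    for comp in sorted(set(groups.values())):
        members = sorted([i for i, g in groups.items() if g == comp], key=rank.get)
        col = f"PC{comp}"
        loads = pca.loadings[col].abs()
        top = max(loads[m] for m in members)
        short = [m for m in members if loads[m] >= (1.0 - shortlist_tol) * top - _EPS]
        short.sort(key=rank.get)
        shortlists[comp] = short
        audit.append(
            f"PC{comp}: members {members}; top |loading| {top:.3f}; "
            f"shortlist (within {shortlist_tol:.0%}) {short}"
        )
        pool = list(short)
        pair_rs = [
            abs(correlations.loc[a, b]) for i, a in enumerate(pool) for b in pool[i + 1:]
        ]
        if pool and (not pair_rs or max(pair_rs) < redundancy_r):
            for i, a in enumerate(pool):
                for b in pool[i + 1:]:
                    audit.append(
                        f"PC{comp}: {a} and {b} retained jointly, "
                        f"|r| = {abs(correlations.loc[a, b]):.3f} < {redundancy_r}"
                    )
            selected.extend(pool)
            continue
        while pool:
            cl = norms.comprehensive_load
            best = max(pool, key=lambda m: (cl[m], -rank[m]))
            selected.append(best)
            dropped = [m for m in pool if m != best and abs(correlations.loc[best, m]) > redundancy_r]
            if dropped:
                audit.append(
                    f"PC{comp}: keep {best} (highest comprehensive load "
                    f"{cl[best]:.3f}); drop redundant {dropped} (|r| > {redundancy_r})"
                )
            pool = [m for m in pool if m != best and m not in dropped]
    selected = sorted(set(selected), key=rank.get)
    audit.append(f"MDS = {selected} (size {len(selected)})")
    return MDSSelection(groups=dict(groups), shortlists=shortlists, selected=selected, audit=audit)


def select_mds_from_samples(samples: SampleTable, config: Config | None = None) -> tuple[MDSSelection, PCAResult, NormScores, pd.DataFrame]:
    """Full data-driven chain: standardize -> PCA -> retain -> Norm -> group -> select.

    Returns the selection plus the intermediate PCA, Norm scores and Pearson
    correlation matrix (useful for reporting).
    """
    cfg = config or Config()
    z = standardize(samples)
    corr = pd.DataFrame(
        np.corrcoef(z.to_numpy(), rowvar=False), index=z.columns, columns=z.columns
    )
    pca = pca_correlation(z)
    retained = retain_components(pca, cfg.eigen_floor, cfg.variance_floor)
    norms = norm_scores(pca, retained)
    audit: list[str] = [f"retained components: {['PC%d' % k for k in retained]}"]
    groups = group_indicators(pca, retained, corr, cfg.loading_cutoff, audit=audit)
    sel = select_mds(
        pca, corr, norms, groups, cfg.shortlist_tol, cfg.redundancy_r, audit=audit
    )
    return sel, pca, norms, corr
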