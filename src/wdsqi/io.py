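"""Table I/O and packaged reference tables.

All tabular interchange is plain CSV with a header row. The packaged
reference tables are the published values this framework was calibrated
against: membership-function breakpoints, per-plot indicator statistics for
the five waste dumps (reclaimed No.1, No.2, No.4_lower; unreclaimed No.3,
No.4_upper), the 9x9 Pearson correlation matrix, the two-component loading
matrix with its "Norm" (comprehensive load) column, communalities/weights,
and the 25 per-sample membership scores.

Transcription notes
-------------------
* The published membership table prints its columns with TN ahead of TP,
  while every other table lists TP first; the source column header is
  ambiguous between the two labels. The fixture keeps the printed order and
  labels; none of the aggregate quantities computed here depend on which of
  the two columns carries which label.
* The published loading table leaves the group of pH blank; the accompanying
  text assigns pH to the first component, which is what ``printed_group``
  records.
* The correlation fixture is stored in the canonical indicator order; the
  source prints the same cells as a lower triangle in a slightly different
  row order.
"""

from __future__ import annotations

import importlib.resources
import logging
import sys
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FixtureLookupError, SchemaError, ValidationError, WdsqiError
from .model import INDICATORS, KEY_COLUMNS, IndicatorSpec, MembershipTable, PlotSummary, SampleTable

log = logging.getLogger("wdsqi")

FIXTURE_IDS = (
    "membership_params",
    "plot_summaries",
    "loadings",
    "correlations",
    "communalities",
    "memberships",
)

#: Published eigenvalues / explained variance of the two retained components.
#: These are *not* reproducible from the printed correlation matrix (whose
#: leading eigenvalues are about 5.61 and 1.21); they evidently derive from
#: the unpublished raw samples. Kept verbatim for reference and testing.
PRINTED_EIGENVALUES = (5.435, 1.204)
PRINTED_VARIANCE_PCT = (60.392, 13.376)
PRINTED_CUMULATIVE_PCT = 73.769

#: Published per-plot improved-Nemerow index values. Not reproducible from
#: the published per-sample memberships under any aggregation tried; retained
#: only for the plot *ordering*, which the pipeline does reproduce.
PRINTED_WDSQIN = {
    "No.4_lower": 0.634,
    "No.1": 0.594,
    "No.2": 0.485,
    "No.3": 0.249,
    "No.4_upper": 0.214,
}

#: Published plot-mean membership scores (2 d.p.), rows in canonical order.
PRINTED_MEAN_MEMBERSHIP = {
    "No.1": {"pH": 0.28, "SOM": 0.85, "AN": 0.80, "AP": 0.78, "AK": 0.98,
             "TN": 0.91, "TP": 0.78, "SMC": 0.78, "BD": 0.73},
    "No.2": {"pH": 0.16, "SOM": 0.86, "AN": 0.78, "AP": 0.68, "AK": 0.98,
             "TN": 0.57, "TP": 0.68, "SMC": 0.59, "BD": 0.46},
    "No.3": {"pH": 0.19, "SOM": 0.22, "AN": 0.19, "AP": 0.41, "AK": 0.75,
             "TN": 0.40, "TP": 0.22, "SMC": 0.49, "BD": 0.44},
    "No.4_upper": {"pH": 0.10, "SOM": 0.12, "AN": 0.16, "AP": 0.34, "AK": 0.62,
                   "TN": 0.19, "TP": 0.18, "SMC": 0.46, "BD": 0.40},
    "No.4_lower": {"pH": 0.31, "SOM": 0.90, "AN": 0.67, "AP": 0.82, "AK": 1.00,
                   "TN": 1.00, "TP": 0.96, "SMC": 0.76, "BD": 0.81},
}


def _data_path(name: str):
    return importlib.resources.files("wdsqi.data") / f"{name}.csv"


def read_sample_table(path, spec_set: Sequence[IndicatorSpec]) -> SampleTable:
    """Read a per-sample indicator CSV and validate it against ``spec_set``.

    The file must contain ``plot_id``, ``sample_id`` and one column per
    indicator named in ``spec_set``; extra columns are ignored. Columns are
    reordered canonically.
    """
    try:
        raw = pd.read_csv(path, dtype={"plot_id": str, "sample_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise WdsqiError(f"cannot read sample table {path}: {exc}") from exc
    names = [s.name for s in spec_set]
    for key in (*KEY_COLUMNS, *names):
        if key not in raw.columns:
            raise SchemaError(f"missing required column {key!r} in {path}")
    for col in names:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise WdsqiError(
                f"non-numeric value {raw[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            raise ValidationError(f"missing value in column {col!r}")
        raw[col] = coerced
    return SampleTable.from_frame(raw, indicators=names)


def write_table(table, path) -> None:
    """Write any of the package's typed tables (or a DataFrame) as CSV.

    Floats carry 12 significant digits so a write/read round-trip is
    value-identical for all practical purposes.
    """
    if isinstance(table, (SampleTable, MembershipTable)):
        frame = table.to_frame()
    elif isinstance(table, pd.DataFrame):
        frame = table.reset_index() if table.index.name or isinstance(
            table.index, pd.MultiIndex
        ) else table
    elif isinstance(table, pd.Series):
        frame = table.rename_axis(table.index.name or "key").reset_index()
    elif isinstance(table, (list, tuple)) and table and isinstance(table[0], IndicatorSpec):
        rows = []
        for s in table:
            p = dict(zip(("p1", "p2", "p3", "p4"), s.params))
            rows.append({"name": s.name, "units": s.units, "fn_kind": s.fn_kind, **p})
        frame = pd.DataFrame(rows)
    elif isinstance(table, (list, tuple)) and table and isinstance(table[0], PlotSummary):
        rows = [
            {"plot_id": ps.plot_id, "indicator": ind, "mean": ps.means[ind], "sd": ps.sds[ind]}
            for ps in table
            for ind in ps.means
        ]
        frame = pd.DataFrame(rows)
    else:
        raise WdsqiError(f"do not know how to serialize {type(table).__name__}")
    try:
        frame.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise WdsqiError(f"cannot write {path}: {exc}") from exc


def load_fixture(table_id: str):
    """Return one packaged reference table, typed.

    ==================  =============================================
    table_id            returns
    ==================  =============================================
    membership_params   list[IndicatorSpec] (canonical order)
    plot_summaries      list[PlotSummary] (five waste dumps)
    loadings            DataFrame indicators x (pc1, pc2, printed_group,
                        printed_norm), canonical order
    correlations        9x9 symmetric DataFrame, unit diagonal
    communalities       DataFrame indicators x (tds_communality,
                        tds_weight, mds_communality, mds_weight)
    memberships         MembershipTable, 25 samples in 5 plots
    ==================  =============================================
    """
    if table_id not in FIXTURE_IDS:
        raise FixtureLookupError(f"unknown fixture {table_id!r}; expected one of {FIXTURE_IDS}")
    path = _data_path(table_id)
    if table_id == "membership_params":
        df = pd.read_csv(path)
        specs = []
        for _, row in df.iterrows():
            params = tuple(row[p] for p in ("p1", "p2", "p3", "p4") if pd.notna(row[p]))
            specs.append(
                IndicatorSpec(row["name"], row["units"], row["fn_kind"], params)
            )
        order = {n: i for i, n in enumerate(INDICATORS)}
        return sorted(specs, key=lambda s: order[s.name])
    if table_id == "plot_summaries":
        df = pd.read_csv(path)
        out = []
        for plot_id, grp in df.groupby("plot_id", sort=False):
            means = dict(zip(grp["indicator"], grp["mean"]))
            sds = dict(zip(grp["indicator"], grp["sd"]))
            out.append(PlotSummary(plot_id, means, sds))
        return out
    if table_id == "loadings":
        df = pd.read_csv(path).set_index("indicator")
        return df.reindex(list(INDICATORS))
    if table_id == "correlations":
        df = pd.read_csv(path).set_index("indicator")
        df.columns.name = "indicator"
        mat = df.reindex(index=list(INDICATORS), columns=list(INDICATORS)).astype(float)
        if not np.allclose(mat.to_numpy(), mat.to_numpy().T):
            raise ValidationError("correlation fixture is not symmetric")
        return mat
    if table_id == "communalities":
        return pd.read_csv(path).set_index("indicator").reindex(list(INDICATORS))
    # memberships
    df = pd.read_csv(path, dtype={"plot_id": str, "sample_id": str})
    ordered = [c for c in INDICATORS if c in df.columns]
    return MembershipTable(df.set_index(list(KEY_COLUMNS))[ordered])


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the given verbosity."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
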