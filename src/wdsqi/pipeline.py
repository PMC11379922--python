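"""End-to-end pipeline: scores -> MDS -> weights -> indices -> classes.

The pipeline is a pure function of (sample table, config); the report embeds
a digest of both so any number in it can be recomputed.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
from dataclasses import dataclass

import pandas as pd

from . import membership as mb
from . import sqi as sq
from .mds import MDSSelection, select_mds_from_samples
from .model import Config, MembershipTable, SampleTable
from .weighting import WeightVector, weights_from_samples

log = logging.getLogger("wdsqi")


@dataclass(frozen=True)
class PipelineReport:
    """Everything the full analysis produces for one sample table."""

    memberships: MembershipTable
    plot_mean_membership: pd.DataFrame
    selection: MDSSelection
    tds_weights: WeightVector
    mds_weights: WeightVector
    wdsqi_tds: sq.SQIResult
    wdsqi_mds: sq.SQIResult
    wdsqin: sq.SQIResult
    mds_vs_tds: sq.RegressionFit
    input_digest: str
    config_digest: str
    timestamp: str

    def summary_table(self) -> pd.DataFrame:
        """Per-plot indices and fertility classes, one row per plot."""
        return pd.DataFrame(
            {
                "wdsqi_tds": self.wdsqi_tds.per_plot,
                "wdsqi_mds": self.wdsqi_mds.per_plot,
                "wdsqin": self.wdsqin.per_plot,
                "class_tds": self.wdsqi_tds.classes,
                "class_mds": self.wdsqi_mds.classes,
                "class_nemerow": self.wdsqin.classes,
            }
        ).rename_axis("plot_id")

    def to_text(self) -> str:
        lines = [
            f"input digest:  {self.input_digest}",
            f"config digest: {self.config_digest}",
            "",
            "MDS selection audit:",
            *(f"  {line}" for line in self.selection.audit),
            "",
            "TDS weights:",
            self.tds_weights.to_frame().round(4).to_string(),
            "",
            "MDS weights:",
            self.mds_weights.to_frame().round(4).to_string(),
            "",
            "Per-plot indices:",
            self.summary_table().round(4).to_string(),
            "",
            f"MDS vs TDS regression: slope {self.mds_vs_tds.slope:.4f}, "
            f"intercept {self.mds_vs_tds.intercept:.4f}, "
            f"R^2 {self.mds_vs_tds.r_squared:.4f}",
        ]
        return "\n".join(lines)


def _digest(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(samples: SampleTable, config: Config | None = None) -> PipelineReport:
    """Execute the whole evaluation chain on one sample table."""
    cfg = config or Config.default()
    if not cfg.specs:
        cfg = cfg.with_specs(Config.default().specs)

    log.info("scoring %d samples x %d indicators", len(samples), len(samples.indicators))
    memberships = mb.score_table(samples, cfg.specs)
    plot_means = mb.plot_mean_membership(memberships)

    selection, _, _, _ = select_mds_from_samples(samples, cfg)
    for line in selection.audit:
        log.info("mds: %s", line)

    tds_w = weights_from_samples(samples, config=cfg, label="TDS")
    mds_w = weights_from_samples(samples, indicators=selection.selected, config=cfg, label="MDS")

    wdsqi_tds = sq.wdsqi_weighted_additive(memberships, tds_w, bounds=cfg.class_bounds)
    wdsqi_mds = sq.wdsqi_weighted_additive(memberships, mds_w, bounds=cfg.class_bounds)
    wdsqin = sq.nemerow_table(memberships, bounds=cfg.class_bounds)
    fit = sq.validate_mds_vs_tds(wdsqi_tds.per_sample, wdsqi_mds.per_sample)

    return PipelineReport(
        memberships=memberships,
        plot_mean_membership=plot_means,
        selection=selection,
        tds_weights=tds_w,
        mds_weights=mds_w,
        wdsqi_tds=wdsqi_tds,
        wdsqi_mds=wdsqi_mds,
        wdsqin=wdsqin,
        mds_vs_tds=fit,
        input_digest=_digest(samples.to_frame().to_csv(index=False)),
        config_digest=_digest(repr(cfg)),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


def export_radar_data(memberships: MembershipTable) -> pd.DataFrame:
    """Plot-ready polygon table: one (plot, indicator, mean membership) row
    per vertex, indicators in canonical order within each plot."""
    means = mb.plot_mean_membership(memberships)
    long = (
        means.reset_index()
        .melt(id_vars="plot_id", var_name="indicator", value_name="mean_membership")
    )
    order = {n: i for i, n in enumerate(means.columns)}
    long["__o"] = long["indicator"].map(order)
    plot_order = {p: i for i, p in enumerate(means.index)}
    long["__p"] = long["plot_id"].map(plot_order)
    return (
        long.sort_values(["__p", "__o"])
        .drop(columns=["__o", "__p"])
        .reset_index(drop=True)
    )
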