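"""End-to-end analysis pipeline: filter -> rarefy -> diversity -> production
-> trends -> phylotype growth.

The pipeline consumes either an on-disk dataset (transect CSV, ASV TSV,
sample map) or a synthetic preset, runs every stage in the analysis order,
writes the per-stage CSV/JSON artefacts, and returns a single report with
the headline quantities: median doubling time, cumulative doublings over the
whole-river travel time, total cell production and its ratio to the standing
stock, whole-river turnover and its contribution to beta diversity, the
headwater-persistence fraction, and the richness/TCC/BSP trends against
travel time. The report embeds the seed and a hash of the configuration,
and is byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import asv_growth, diversity, production, synthetic, trends
from .errors import ConfigError
from .transect import read_transect_csv

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

REPORT_KEYS = [
    "median_doubling_time_days",
    "cumulative_divisions",
    "cp_tot_cells_per_l",
    "standing_stock_ratio",
    "whole_river_turnover",
    "turnover_contribution_pct",
    "headwater_persistence",
    "richness_slope_asv_per_h",
    "tcc_slope_cells_per_l_h",
    "bsp_slope_ugc_per_l_h2",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``preset`` (synthetic data) or all three input paths must be set.
    ``min_reads``/``depth``/``reps`` control library screening and
    rarefaction; ``None`` depth means "rarefy to the smallest retained
    library". Thresholds mirror the module defaults they feed.
    """

    preset: str | None = None
    transect_csv: str | None = None
    asv_tsv: str | None = None
    sample_map_csv: str | None = None
    out_dir: str = "lotic_out"
    seed: int = 0
    min_reads: int = 3155
    depth: int | None = None
    reps: int = 50
    biomass_factor: float = 310.0
    n_head: int = 3
    presence_frac: float = 0.9
    turnover_method: str = "endpoints"
    select_min_ratio: float = 100.0
    select_min_max_abund: float = 0.01
    select_min_prevalence: int = 20
    max_growth_asvs: int = 8
    basis_dim: int = 10

    def validate(self) -> None:
        has_files = all((self.transect_csv, self.asv_tsv, self.sample_map_csv))
        if not (self.preset or has_files):
            raise ConfigError("need a preset or transect/ASV/sample-map paths")
        if self.preset and self.preset not in synthetic.PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        for name in ("min_reads", "reps", "n_head", "max_growth_asvs", "basis_dim"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.depth is not None and self.depth <= 0:
            raise ConfigError("depth must be positive")
        for p in (self.transect_csv, self.asv_tsv, self.sample_map_csv):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.preset:
        truth = synthetic.PRESETS[config.preset](seed=config.seed)
        transect = synthetic.generate_transect(truth)
        table = synthetic.generate_asv_table(truth, transect)
        return transect, table
    transect = read_transect_csv(config.transect_csv)
    table = diversity.AsvTable.from_tsv(config.asv_tsv, config.sample_map_csv)
    return transect, table


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report dict; raises the originating error (annotated with
    the stage name) if any stage fails.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    stage = "load"
    try:
        transect, table = _load_inputs(config)

        stage = "filter"
        table = diversity.drop_shallow(table, config.min_reads)
        depth = config.depth or int(table.counts.sum(axis=0).min())
        stage = "rarefy"
        rarefied = diversity.rarefy(table, depth=depth, reps=config.reps,
                                    seed=config.seed)

        stage = "diversity"
        richness = diversity.observed_asvs(rarefied)
        series = diversity.consecutive_series(rarefied, transect, "partition")
        series.to_csv(out / "consecutive_partition.csv", index=False)
        wrt = diversity.whole_river_turnover(rarefied, transect,
                                             method=config.turnover_method)
        persistence = diversity.headwater_persistence(
            rarefied, transect, n_head=config.n_head,
            presence_frac=config.presence_frac,
        )

        stage = "production"
        profile = production.build_profile(
            transect,
            conversion=production.LinearVolumeCarbon(config.biomass_factor),
        )
        profile.to_csv(out / "production_sites.csv", out / "production_segments.csv")
        prod_summary = profile.summary()

        stage = "trends"
        tt = transect.tt_cum
        site_order = transect.site_ids
        rich_by_site = np.array(
            [richness[rarefied.site_sample(s)] for s in site_order], dtype=float
        )
        fit_rich = trends.fit_linear(tt, rich_by_site, "tt_cum_h", "observed_asvs")
        fit_tcc = trends.fit_linear(tt, transect.values("tcc"), "tt_cum_h", "tcc")
        fit_bsp = trends.fit_linear(tt, transect.values("bsp"), "tt_cum_h", "bsp")
        tidy = (
            fit_rich.to_tidy()
            .merge(fit_tcc.to_tidy(), how="outer")
            .merge(fit_bsp.to_tidy(), how="outer")
        )
        tidy.to_csv(out / "trend_models.csv", index=False)

        stage = "growth"
        rel = diversity.relative_abundance(rarefied)
        rel = rel[[rarefied.site_sample(s) for s in site_order]]
        selected = asv_growth.select_asvs(
            rel,
            min_ratio=config.select_min_ratio,
            min_max_abund=config.select_min_max_abund,
            min_prevalence=config.select_min_prevalence,
        )
        # keep the runtime bounded: fit the most abundant selected phylotypes
        selected = sorted(
            selected, key=lambda a: -float(rel.loc[a].max())
        )[: config.max_growth_asvs]
        growth = asv_growth.growth_table(
            rel,
            tcc=profile.site_table.set_index("site_id")["tcc"].loc[site_order],
            tt=profile.site_table.set_index("site_id")["tt_cum_h"].loc[site_order],
            bulk_cd_daily=prod_summary["median_cd_daily"],
            asv_ids=selected,
            basis_dim=config.basis_dim,
        )
        growth.to_csv(out / "growth_summary.csv", index=False)
    except Exception as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc

    report = {
        **stamp,
        "n_sites": len(transect.sites),
        "n_samples": len(table.sample_ids),
        "rarefaction_depth": depth,
        "rarefaction_reps": config.reps,
        "median_doubling_time_days": prod_summary["median_doubling_time_days"],
        "median_cd_daily": prod_summary["median_cd_daily"],
        "total_travel_time_days": prod_summary["total_travel_time_days"],
        "cumulative_divisions": prod_summary["cumulative_divisions"],
        "cumulative_divisions_segmentwise": prod_summary["cumulative_divisions_segmentwise"],
        "cp_tot_cells_per_l": prod_summary["cp_tot_cells_per_l"],
        "standing_stock_ratio": prod_summary["standing_stock_ratio"],
        "whole_river_turnover": wrt.turnover,
        "turnover_contribution_pct": wrt.percent_contribution,
        "turnover_method": wrt.method,
        "headwater_persistence": persistence.fraction,
        "headwater_pool_size": persistence.pool_size,
        "richness_slope_asv_per_h": fit_rich.slope,
        "richness_slope_se": fit_rich.slope_se,
        "tcc_slope_cells_per_l_h": fit_tcc.slope,
        "tcc_slope_se": fit_tcc.slope_se,
        "bsp_slope_ugc_per_l_h2": fit_bsp.slope,
        "bsp_slope_se": fit_bsp.slope_se,
        "n_growth_asvs": int(len(growth)),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
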