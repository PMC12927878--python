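"""Synthetic river transects and ASV tables with known ground truth.

The generator emulates the statistical structure of a summer whole-river
survey of a large, regulated continental river:

* a downstream-ordered transect whose flow velocities decline towards the
  impounded lower course, giving a total water travel time of a few weeks;
* total cell counts (TCC) increasing, and bulk secondary production (BSP),
  mean cell volumes and ASV richness decreasing, linearly in cumulative
  travel time, with mean-one lognormal measurement noise;
* a community that is *replaced* rather than thinned along the river:
  each non-persistent phylotype is exchanged for a fresh one with a fixed
  per-segment probability, while a small persistent headwater core is never
  replaced -- the simplest generative process producing turnover-dominated,
  nestedness-minor beta-diversity partitions;
* a handful of "bloomer" phylotypes following logistic trajectories whose
  exponential phase runs at a large multiple of the bulk division rate;
* multinomial read sampling at a fixed depth per sample.

Everything is deterministic under (seed, parameters); the planted parameters
and the derived expectations needed for recovery tests are exported by
:func:`truth_report`.

The uppermost ``n_headwater_shared`` sites are modelled as a single
headwater reach draining one source pool: replacement starts downstream of
it (species loss still applies within it). This makes the planted
``persistent_fraction`` exactly the quantity the headwater-persistence
analysis estimates, because the headwater ASV pool then coincides with the
first site's community instead of being inflated by within-reach turnover.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from ._util import substream
from .diversity import AsvTable
from .errors import ConfigError
from .transect import Site, Transect, build_transect

__all__ = [
    "SyntheticTruth",
    "jds3like",
    "jds2like",
    "strong_replacement",
    "generate_transect",
    "generate_asv_table",
    "truth_report",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters of one synthetic river dataset.

    Units: lengths km, velocities km/h, travel time hours, TCC cells/l,
    BSP ugC/l/h, cell volume um^3. Slopes are per travel-hour. Noise SDs are
    the sigma of mean-one lognormal multiplicative noise, except
    ``richness_noise_sd`` which is additive (ASVs).
    """

    seed: int = 0
    n_sites: int = 54
    total_length_km: float = 2563.0
    rkm_start: float = 2581.0
    velocity_start: float = 4.0
    velocity_end: float = 1.0
    velocity_min: float = 0.9
    velocity_max: float = 5.4
    tcc_intercept: float = 1.008e10
    tcc_slope: float = 9.5e6
    bsp_intercept: float = 1.467
    bsp_slope: float = -7.9e-4
    volume_start: float = 0.0677
    volume_end: float = 0.025
    richness_start: int = 400
    richness_slope: float = -0.13
    richness_noise_sd: float = 10.0
    replacement_rate: float = 0.30
    persistent_fraction: float = 0.10
    n_headwater_shared: int = 3
    n_bloomers: int = 4
    bloomer_rate_multiplier: float = 100.0
    bloomer_carrying_frac: float = 0.08
    bulk_cd_daily: float = 0.12
    tcc_noise_sd: float = 0.25
    bsp_noise_sd: float = 0.30
    volume_noise_sd: float = 0.15
    abundance_sigma: float = 0.8
    depth: int = 50_000

    # -- derived helpers --------------------------------------------------
    @property
    def velocity_profile(self) -> np.ndarray:
        v = np.linspace(self.velocity_start, self.velocity_end, self.n_sites)
        return np.clip(v, self.velocity_min, self.velocity_max)

    @property
    def n_core(self) -> int:
        return int(round(self.persistent_fraction * self.richness_start))

    def validate(self) -> None:
        if self.n_sites < 3:
            raise ConfigError("n_sites must be >= 3")
        if not (0 <= self.replacement_rate <= 1):
            raise ConfigError("replacement_rate must be in [0, 1]")
        if not (0 <= self.persistent_fraction <= 1):
            raise ConfigError("persistent_fraction must be in [0, 1]")
        if self.depth < 50 * self.richness_start:
            raise ConfigError("depth must be >= 50x richness_start for the "
                              "planted richness to be observable")
        tt_total = _tt_cum(self)[-1]
        if self.richness_start <= abs(self.richness_slope) * tt_total:
            raise ConfigError("richness would hit zero along the transect")
        if self.bsp_intercept + self.bsp_slope * tt_total <= 0:
            raise ConfigError("BSP would turn negative along the transect")
        if self.tcc_intercept + min(0.0, self.tcc_slope) * tt_total <= 0:
            raise ConfigError("TCC would turn negative along the transect")
        if min(self.volume_start, self.volume_end) <= 0:
            raise ConfigError("cell volumes must stay positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


def jds3like(seed: int = 0, **overrides) -> SyntheticTruth:
    """Low-flow survey preset: 54 sites, velocities 0.9-5.4 km/h, ~50 days."""
    return replace(SyntheticTruth(seed=seed), **overrides)


def jds2like(seed: int = 0, **overrides) -> SyntheticTruth:
    """Mean-flow survey preset: 75 sites, faster water, ~31 days."""
    base = SyntheticTruth(
        seed=seed,
        n_sites=75,
        total_length_km=2582.0,
        rkm_start=2600.0,
        velocity_start=6.0,
        velocity_end=1.8,
        velocity_min=0.6,
        velocity_max=11.2,
        tcc_intercept=1.464e9,
        tcc_slope=0.93e6,
        bsp_intercept=0.471,
        bsp_slope=-5.7e-4,
        volume_start=0.1469,
        volume_end=0.07,
        richness_start=350,
        richness_slope=-0.145,
    )
    return replace(base, **overrides)


def strong_replacement(seed: int = 0, **overrides) -> SyntheticTruth:
    """Species-sorting scenario with near-complete phylotype exchange.

    High per-segment replacement and a small persistent core, the regime in
    which whole-river turnover approaches 1 and dominates beta diversity.
    """
    return jds3like(seed=seed, replacement_rate=0.5, persistent_fraction=0.03,
                    **overrides)


PRESETS = {
    "jds3like": jds3like,
    "jds2like": jds2like,
    "strong_replacement": strong_replacement,
}


# ---------------------------------------------------------------------------
# Transect generation
# ---------------------------------------------------------------------------

def _tt_cum(truth: SyntheticTruth) -> np.ndarray:
    """Deterministic cumulative travel time implied by the velocity profile."""
    v = truth.velocity_profile
    d = truth.total_length_km / (truth.n_sites - 1)
    seg_v = 0.5 * (v[:-1] + v[1:])
    return np.concatenate([[0.0], np.cumsum(d / seg_v)])


def _lognoise(rng, sd, size):
    """Mean-one multiplicative lognormal noise (bias-corrected)."""
    if sd <= 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=size)


def generate_transect(truth: SyntheticTruth) -> Transect:
    """Generate the site metadata table and assemble the transect.

    Velocities (and therefore travel times) are deterministic; measured
    quantities carry mean-one lognormal noise so that ordinary least squares
    on the planted linear trends is unbiased.
    """
    truth.validate()
    rng = substream(truth.seed, "transect")
    n = truth.n_sites
    tt = _tt_cum(truth)
    tt_total = tt[-1]
    v = truth.velocity_profile
    d = truth.total_length_km / (n - 1)
    frac = tt / tt_total

    tcc = (truth.tcc_intercept + truth.tcc_slope * tt) * _lognoise(rng, truth.tcc_noise_sd, n)
    bsp = (truth.bsp_intercept + truth.bsp_slope * tt) * _lognoise(rng, truth.bsp_noise_sd, n)
    vol = (truth.volume_start + (truth.volume_end - truth.volume_start) * frac) * _lognoise(
        rng, truth.volume_noise_sd, n
    )
    # Environmental covariates: broad-strokes summer river chemistry.
    nitrate = (12.0 - 8.1 * frac) * _lognoise(rng, 0.10, n)
    chla = (2.0 + 12.0 * np.exp(-0.5 * ((frac - 0.55) / 0.18) ** 2)) * _lognoise(rng, 0.25, n)
    discharge = (500.0 + 6000.0 * frac) * _lognoise(rng, 0.10, n)
    temperature = 21.0 + rng.normal(0.0, 0.8, n)

    sites = []
    for i in range(n):
        sites.append(
            Site(
                site_id=f"S{i + 1:03d}",
                rkm=truth.rkm_start - i * d,
                velocity=float(v[i]),
                tcc=float(tcc[i]),
                bsp=float(bsp[i]),
                mean_cell_volume=float(vol[i]),
                nitrate=float(nitrate[i]),
                chlorophyll_a=float(chla[i]),
                discharge=float(discharge[i]),
                temperature=float(temperature[i]),
            )
        )
    return build_transect(sites, [d] * (n - 1), velocity_rule="mean")


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

def _bloomer_t0(truth: SyntheticTruth, tt_total: float) -> np.ndarray:
    if truth.n_bloomers == 0:
        return np.empty(0)
    pos = np.linspace(0.35, 0.85, truth.n_bloomers)
    return pos * tt_total


def _bloomer_rel(truth: SyntheticTruth, tt: np.ndarray) -> np.ndarray:
    """Expected relative abundance of each bloomer at each site (nb x n)."""
    g = truth.bloomer_rate_multiplier * truth.bulk_cd_daily / 24.0  # per hour
    t0 = _bloomer_t0(truth, tt[-1])
    if t0.size == 0:
        return np.zeros((0, len(tt)))
    z = -g * (tt[None, :] - t0[:, None])
    with np.errstate(over="ignore"):
        rel = truth.bloomer_carrying_frac / (1.0 + np.exp(z))
    rel[rel < 1e-12] = 0.0
    return rel


def generate_asv_table(truth: SyntheticTruth, transect: Transect) -> AsvTable:
    """Generate the ASV x sample count table for a transect.

    The headwater community holds ``richness_start`` phylotypes with
    lognormal abundance weights; a ``persistent_fraction`` core is exempt
    from both replacement and loss. Downstream of the shared headwater
    reach, every non-core member is replaced with probability
    ``replacement_rate`` per segment, and the community is then adjusted to
    the (noisy) target richness ``richness_start + richness_slope * tt`` by
    random loss or recruitment of non-core phylotypes. Bloomers are overlaid
    as logistic relative-abundance trajectories, and each sample draws
    exactly ``depth`` multinomial reads.
    """
    truth.validate()
    rng = substream(truth.seed, "asvtable")
    tt = transect.tt_cum
    n = truth.n_sites
    if len(tt) != n:
        raise ConfigError("transect does not match truth.n_sites")

    targets = np.round(
        truth.richness_start
        + truth.richness_slope * tt
        + rng.normal(0.0, truth.richness_noise_sd, n)
    ).astype(int)
    targets[0] = truth.richness_start
    n_core = truth.n_core
    targets = np.maximum(targets, n_core + 5)

    next_id = truth.richness_start
    members = list(range(truth.richness_start))
    core = set(rng.choice(truth.richness_start, size=n_core, replace=False).tolist())

    bloom_rel = _bloomer_rel(truth, tt)
    # Bloomers are community members too: where a bloomer is abundant enough
    # to be detected at the sample depth it occupies one slot of the site's
    # richness target, so the planted richness trend stays unbiased.
    bloom_present = (bloom_rel * truth.depth > 5.0).sum(axis=0).astype(int)
    site_members: list[list[int]] = []
    for k in range(n):
        if k > 0:
            if k >= truth.n_headwater_shared:
                fresh = []
                kept = []
                draws = rng.random(len(members))
                for m, u in zip(members, draws):
                    if m not in core and u < truth.replacement_rate:
                        fresh.append(next_id)
                        next_id += 1
                    else:
                        kept.append(m)
                members = kept + fresh
            # enforce the (noisy) richness target by loss or recruitment
            non_core = [m for m in members if m not in core]
            excess = len(members) + bloom_present[k] - targets[k]
            if excess > 0:
                drop = set(
                    rng.choice(len(non_core), size=min(excess, len(non_core)),
                               replace=False).tolist()
                )
                non_core = [m for i, m in enumerate(non_core) if i not in drop]
                members = [m for m in members if m in core] + non_core
            elif excess < 0:
                members = members + list(range(next_id, next_id - excess))
                next_id += -excess
        site_members.append(list(members))

    # assemble the count matrix
    all_ids = sorted(set().union(*site_members))
    index = {m: i for i, m in enumerate(all_ids)}
    nb = truth.n_bloomers
    counts = np.zeros((len(all_ids) + nb, n), dtype=np.int64)
    for k in range(n):
        mem = site_members[k]
        w = rng.lognormal(0.0, truth.abundance_sigma, len(mem))
        brel = bloom_rel[:, k] if nb else np.empty(0)
        btot = float(brel.sum())
        if btot >= 0.5:  # cap combined bloomer share
            brel = brel * (0.5 / btot)
            btot = 0.5
        p = np.zeros(counts.shape[0])
        p[[index[m] for m in mem]] = w / w.sum() * (1.0 - btot)
        if nb:
            p[len(all_ids):] = brel
        draw = rng.multinomial(truth.depth, p / p.sum())
        counts[:, k] = draw

    asv_ids = [f"ASV_{m + 1:05d}" for m in all_ids] + [
        f"ASV_B{j + 1}" for j in range(nb)
    ]
    sample_ids = [f"SMP_{s}" for s in transect.site_ids]
    frame = pd.DataFrame(counts, index=asv_ids, columns=sample_ids)
    mapping = dict(zip(sample_ids, transect.site_ids))
    return AsvTable(counts=frame, sample_to_site=mapping, fraction_label="bulk")


def truth_report(truth: SyntheticTruth) -> dict:
    """Machine-readable ground truth: parameters plus derived expectations.

    The derived block contains the deterministic travel-time axis, the
    expected (noise-free) richness per site, the expected consecutive-site
    turnover ``replacement_rate * (1 - core share)`` per segment (zero
    within the shared headwater reach; first-order in the within-segment
    richness change), and the planted bloomer trajectories.
    """
    truth.validate()
    tt = _tt_cum(truth)
    exp_rich = truth.richness_start + truth.richness_slope * tt
    n_core = truth.n_core
    seg_turnover = []
    for i in range(truth.n_sites - 1):
        if i + 1 < truth.n_headwater_shared:
            seg_turnover.append(0.0)
        else:
            seg_turnover.append(
                truth.replacement_rate * (1.0 - n_core / exp_rich[i])
            )
    g = truth.bloomer_rate_multiplier * truth.bulk_cd_daily / 24.0
    return {
        "parameters": asdict(truth),
        "expected": {
            "tt_cum_h": tt.tolist(),
            "total_travel_time_days": float(tt[-1] / 24.0),
            "expected_richness": exp_rich.tolist(),
            "expected_segment_turnover": seg_turnover,
            "n_core": n_core,
            "bloomer_growth_rate_per_h": g,
            "bloomer_t0_h": _bloomer_t0(truth, tt[-1]).tolist(),
            "bloomer_relative_trajectories": _bloomer_rel(truth, tt).tolist(),
            "expected_tcc": (truth.tcc_intercept + truth.tcc_slope * tt).tolist(),
        },
    }


def write_dataset(truth: SyntheticTruth, out_dir) -> dict:
    """Write transect CSV, ASV TSV, sample map CSV and truth JSON to a directory."""
    from pathlib import Path

    from .transect import write_transect_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transect = generate_transect(truth)
    table = generate_asv_table(truth, transect)
    paths = {
        "transect": out / "transect.csv",
        "asv_table": out / "asv_table.tsv",
        "sample_map": out / "sample_map.csv",
        "truth": out / "truth.json",
    }
    write_transect_csv(transect, paths["transect"], meta=f"seed={truth.seed}")
    table.to_tsv(paths["asv_table"], paths["sample_map"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_report(truth), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
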