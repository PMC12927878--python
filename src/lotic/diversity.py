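"""ASV tables, rarefaction, and beta-diversity partitioning.

The community data structure is an integer count matrix (ASVs x samples) with
a sample-to-site map tying it to a :class:`~lotic.transect.Transect`. The
analysis chain mirrors the standard amplicon workflow for river transects:

1. discard shallow libraries (:func:`drop_shallow`),
2. rarefy by repeated resampling with replacement to a common depth and
   average the repetitions (:func:`rarefy`),
3. richness as the count of observed ASVs (:func:`observed_asvs`),
4. Bray-Curtis dissimilarity on per-sample-normalized abundances,
5. partition pairwise Sorensen dissimilarity into its Simpson *turnover*
   (species replacement) and *nestedness* (species loss) components,
6. summarise turnover along the whole river and the persistence of
   headwater-associated ASVs downstream.

The partition identity ``beta_sor = beta_sim + beta_nes`` holds exactly: with
``a`` shared species and ``b, c`` species unique to either community,

    beta_sim = min(b, c) / (a + min(b, c))
    beta_sor = (b + c) / (2a + b + c)
    beta_nes = beta_sor - beta_sim
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import round_half_away, substream
from .errors import (
    EmptyResultError,
    InvalidInputError,
    MappingError,
)
from .transect import Transect

__all__ = [
    "AsvTable",
    "BetaPartition",
    "drop_shallow",
    "rarefy",
    "observed_asvs",
    "relative_abundance",
    "bray_curtis",
    "beta_partition_pair",
    "pairwise_dissimilarity",
    "consecutive_series",
    "whole_river_turnover",
    "WholeRiverTurnover",
    "headwater_persistence",
    "PersistenceResult",
]

log = logging.getLogger(__name__)


@dataclass
class AsvTable:
    """Integer ASV x sample count matrix with a sample-to-site map.

    ``counts`` rows are ASV ids, columns are sample ids. ``sample_to_site``
    maps every column to a transect site id. ``fraction_label`` records which
    size fraction the samples represent (``bulk``, ``FL`` free-living or
    ``PA`` particle-associated).
    """

    counts: pd.DataFrame
    sample_to_site: dict[str, str]
    fraction_label: str = "bulk"

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise InvalidInputError("counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise InvalidInputError("counts must be integers")
        missing = [c for c in self.counts.columns if c not in self.sample_to_site]
        if missing:
            raise MappingError(f"samples without site mapping: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    def site_sample(self, site_id: str) -> str:
        """The unique sample belonging to ``site_id`` (error otherwise)."""
        hits = [s for s in self.counts.columns if self.sample_to_site[s] == site_id]
        if len(hits) != 1:
            raise MappingError(
                f"site {site_id!r} has {len(hits)} samples, expected exactly 1"
            )
        return hits[0]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path, sample_map_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="asv_id")
        if sample_map_path is not None:
            pd.DataFrame(
                {
                    "sample_id": list(self.counts.columns),
                    "site_id": [self.sample_to_site[s] for s in self.counts.columns],
                    "fraction": self.fraction_label,
                }
            ).to_csv(sample_map_path, index=False)

    @classmethod
    def from_tsv(cls, counts_path, sample_map_path) -> "AsvTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="asv_id")
        smap = pd.read_csv(sample_map_path, dtype=str)
        mapping = dict(zip(smap["sample_id"], smap["site_id"]))
        fraction = smap["fraction"].iloc[0] if "fraction" in smap else "bulk"
        return cls(counts=counts.astype(np.int64), sample_to_site=mapping,
                   fraction_label=str(fraction))


@dataclass(frozen=True)
class BetaPartition:
    """Pairwise Sorensen dissimilarity split into turnover and nestedness."""

    beta_sor: float
    beta_sim: float
    beta_nes: float
    pair: tuple[str, str] | None = None


def drop_shallow(table: AsvTable, min_reads: int, prune_empty: bool = True) -> AsvTable:
    """Remove samples with fewer than ``min_reads`` total reads.

    ASV rows that become all-zero are pruned by default. Every dropped
    sample is logged together with the rule that dropped it.
    """
    if min_reads <= 0:
        raise InvalidInputError("min_reads must be > 0")
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_reads].index
    dropped = [s for s in table.counts.columns if s not in set(keep)]
    for s in dropped:
        log.info("drop_shallow: removed sample %s (%d < %d reads)", s, totals[s], min_reads)
    if len(keep) == 0:
        raise EmptyResultError(f"all samples have < {min_reads} reads")
    counts = table.counts[keep]
    if prune_empty:
        nonzero = counts.sum(axis=1) > 0
        n_pruned = int((~nonzero).sum())
        if n_pruned:
            log.info("drop_shallow: pruned %d all-zero ASV rows", n_pruned)
        counts = counts.loc[nonzero]
    mapping = {s: table.sample_to_site[s] for s in keep}
    return AsvTable(counts=counts, sample_to_site=mapping,
                    fraction_label=table.fraction_label)


def _rarefy_reps(counts: np.ndarray, depth: int, reps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Resample one sample with replacement ``reps`` times to exactly ``depth``.

    Returns a (reps, n_asv) integer matrix; every row sums to ``depth``
    exactly, by construction of the multinomial draw.
    """
    total = counts.sum()
    if total <= 0:
        raise InvalidInputError("cannot rarefy an empty sample")
    p = counts / total
    return rng.multinomial(depth, p, size=reps)


def rarefy(
    table: AsvTable,
    depth: int,
    reps: int = 50,
    seed: int = 0,
    return_reps: bool = False,
):
    """Rarefy every sample to ``depth`` reads, ``reps`` times, and average.

    Each sample is independently resampled *with replacement* to exactly
    ``depth`` reads in each repetition; the returned counts are the per-cell
    means across repetitions, rounded half away from zero (so column totals
    are close to, but not exactly, ``depth``). Samples shallower than
    ``depth`` must be removed first with :func:`drop_shallow`.

    Randomness is reproducible: the master ``seed`` is expanded into one
    substream per sample, keyed by the sample id, so adding or removing a
    sample never perturbs another sample's draws.

    With ``return_reps=True`` additionally returns ``{sample_id: (reps,
    n_asv) int matrix}`` of the raw repetitions.
    """
    if depth <= 0:
        raise InvalidInputError("depth must be > 0")
    if reps <= 0:
        raise InvalidInputError("reps must be > 0")
    out = {}
    rep_stacks = {}
    for s in table.counts.columns:
        col = table.counts[s].to_numpy(dtype=float)
        if col.sum() < depth:
            raise InvalidInputError(
                f"sample {s} has {int(col.sum())} < depth {depth} reads; "
                "run drop_shallow first"
            )
        rng = substream(seed, f"rarefy/{s}")
        stack = _rarefy_reps(col, depth, reps, rng)
        if return_reps:
            rep_stacks[s] = stack
        out[s] = round_half_away(stack.mean(axis=0)).astype(np.int64)
    counts = pd.DataFrame(out, index=table.counts.index)
    result = AsvTable(counts=counts, sample_to_site=dict(table.sample_to_site),
                      fraction_label=table.fraction_label)
    if return_reps:
        return result, rep_stacks
    return result


def observed_asvs(data):
    """Richness: the number of ASVs with count > 0.

    Accepts a single count vector (returns an int) or an :class:`AsvTable` /
    DataFrame (returns a per-sample Series).
    """
    if isinstance(data, AsvTable):
        return (data.counts > 0).sum(axis=0)
    if isinstance(data, pd.DataFrame):
        return (data > 0).sum(axis=0)
    arr = np.asarray(data)
    return int(np.count_nonzero(arr > 0))


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    if np.any(totals.to_numpy() <= 0):
        raise InvalidInputError("zero-read sample: drop before normalizing")
    return table.counts / totals


def bray_curtis(x, y, atol: float = 1e-9) -> float:
    """Bray-Curtis dissimilarity between two normalized abundance vectors.

    Both inputs must be non-negative and sum to 1 within ``atol``; the value
    is 1 - 2*sum(min(x,y)) / sum(x+y), symmetric and in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("abundances must be >= 0")
    if abs(x.sum() - 1.0) > atol or abs(y.sum() - 1.0) > atol:
        raise InvalidInputError("inputs must each sum to 1 (normalize first)")
    denom = np.sum(x + y)
    return float(1.0 - 2.0 * np.sum(np.minimum(x, y)) / denom)


def beta_partition_pair(x, y, pair: tuple[str, str] | None = None) -> BetaPartition:
    """Partition the Sorensen dissimilarity of two presence vectors.

    ``x`` and ``y`` are binary (or truthy count) vectors of equal length;
    each community must contain at least one species.
    """
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise InvalidInputError("vectors must have equal length")
    if not x.any() or not y.any():
        raise InvalidInputError("each community must contain at least one species")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    beta_sor = (b + c) / (2 * a + b + c)
    return BetaPartition(beta_sor=beta_sor, beta_sim=beta_sim,
                         beta_nes=beta_sor - beta_sim, pair=pair)


def pairwise_dissimilarity(table: AsvTable) -> pd.DataFrame:
    """All pairwise partitions + Bray-Curtis, long format.

    Columns: sample_i, sample_j, beta_sor, beta_sim, beta_nes, bray_curtis.
    """
    rel = relative_abundance(table)
    samples = list(table.counts.columns)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            si, sj = samples[i], samples[j]
            part = beta_partition_pair(table.counts[si], table.counts[sj], (si, sj))
            rows.append(
                {
                    "sample_i": si,
                    "sample_j": sj,
                    "beta_sor": part.beta_sor,
                    "beta_sim": part.beta_sim,
                    "beta_nes": part.beta_nes,
                    "bray_curtis": bray_curtis(rel[si], rel[sj]),
                }
            )
    return pd.DataFrame(rows)


def _ordered_samples(table: AsvTable, transect: Transect) -> list[str]:
    return [table.site_sample(sid) for sid in transect.site_ids]


def consecutive_series(
    table: AsvTable, transect: Transect, metric: str = "partition"
) -> pd.DataFrame:
    """Dissimilarity between consecutive sites, ordered by travel time.

    Each record carries the pair's midpoint cumulative travel time
    (``tt_mid_h``) for use as the regression axis. ``metric`` is
    ``"partition"`` (Sorensen/Simpson/nestedness) or ``"bray_curtis"``.
    """
    if metric not in ("partition", "bray_curtis"):
        raise InvalidInputError(f"unknown metric {metric!r}")
    samples = _ordered_samples(table, transect)
    tt = transect.tt_cum
    rel = relative_abundance(table) if metric == "bray_curtis" else None
    rows = []
    for i in range(len(samples) - 1):
        si, sj = samples[i], samples[i + 1]
        row = {
            "upstream_site": transect.site_ids[i],
            "downstream_site": transect.site_ids[i + 1],
            "tt_mid_h": 0.5 * (tt[i] + tt[i + 1]),
        }
        if metric == "partition":
            part = beta_partition_pair(table.counts[si], table.counts[sj], (si, sj))
            row.update(beta_sor=part.beta_sor, beta_sim=part.beta_sim,
                       beta_nes=part.beta_nes)
        else:
            row["bray_curtis"] = bray_curtis(rel[si], rel[sj])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WholeRiverTurnover:
    turnover: float
    percent_contribution: float
    method: str
    degenerate: bool = False  # endpoints identical: contribution undefined, reported 0


def whole_river_turnover(
    table: AsvTable, transect: Transect, method: str = "endpoints"
) -> WholeRiverTurnover:
    """Turnover over the entire river and its share of total beta diversity.

    ``endpoints`` (default) partitions the first-vs-last site pair;
    ``multisite`` computes the Baselga multiple-site Simpson/Sorensen over
    all sites (min/max unique-species numerators summed across pairs).
    ``percent_contribution`` is turnover / Sorensen x 100.
    """
    samples = _ordered_samples(table, transect)
    pres = table.counts[samples].to_numpy() > 0
    if method == "endpoints":
        part = beta_partition_pair(pres[:, 0], pres[:, -1])
        if part.beta_sor == 0.0:
            return WholeRiverTurnover(0.0, 0.0, method, degenerate=True)
        return WholeRiverTurnover(
            part.beta_sim, 100.0 * part.beta_sim / part.beta_sor, method
        )
    if method == "multisite":
        n = pres.shape[1]
        s_i = pres.sum(axis=0)
        s_t = int(np.any(pres, axis=1).sum())
        sum_min = 0
        sum_max = 0
        for i in range(n):
            for j in range(i + 1, n):
                b_ij = int(np.sum(pres[:, i] & ~pres[:, j]))
                b_ji = int(np.sum(~pres[:, i] & pres[:, j]))
                sum_min += min(b_ij, b_ji)
                sum_max += max(b_ij, b_ji)
        a_comp = int(s_i.sum()) - s_t
        if sum_min + sum_max == 0:
            return WholeRiverTurnover(0.0, 0.0, method, degenerate=True)
        beta_sim = sum_min / (a_comp + sum_min)
        beta_sor = (sum_min + sum_max) / (2 * a_comp + sum_min + sum_max)
        return WholeRiverTurnover(beta_sim, 100.0 * beta_sim / beta_sor, method)
    raise InvalidInputError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PersistenceResult:
    fraction: float
    pool_size: int
    n_persistent: int
    n_downstream_samples: int


def headwater_persistence(
    table: AsvTable,
    transect: Transect,
    n_head: int = 3,
    presence_frac: float = 0.9,
) -> PersistenceResult:
    """Fraction of headwater-associated ASVs persisting downstream.

    The headwater pool is every ASV present in any of the ``n_head``
    uppermost-site samples; a pool member persists if it is present in at
    least ``presence_frac`` of all downstream samples.
    """
    if not (0 < n_head < len(transect.sites)):
        raise InvalidInputError("n_head must be between 1 and n_sites - 1")
    if not (0 < presence_frac <= 1):
        raise InvalidInputError("presence_frac must be in (0, 1]")
    samples = _ordered_samples(table, transect)
    head, down = samples[:n_head], samples[n_head:]
    pres = table.counts > 0
    pool = pres[head].any(axis=1)
    pool_size = int(pool.sum())
    if pool_size == 0:
        raise EmptyResultError("headwater pool is empty")
    down_frac = pres[down].sum(axis=1) / len(down)
    persistent = pool & (down_frac >= presence_frac)
    n_pers = int(persistent.sum())
    return PersistenceResult(
        fraction=n_pers / pool_size,
        pool_size=pool_size,
        n_persistent=n_pers,
        n_downstream_samples=len(down),
    )
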