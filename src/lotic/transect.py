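"""Downstream-ordered river transects and water travel time (WTT).

A transect is an ordered chain of sampling sites along a river main stem,
headwater first, ordered by strictly decreasing river kilometre (rkm counts
upstream from the mouth, so rkm 2581 near the source and rkm 18 near the
mouth). Each adjacent pair of sites defines a segment with a distance and a
representative flow velocity; the segment travel time is distance / velocity
and the cumulative travel time ``tt_cum`` is the prefix sum of segment times,
zero at the first site. Travel times are stored in hours; day-denominated
quantities convert by 24 at presentation time only.

Water travel time is the central predictor of the whole analysis: cell
counts, production, richness and community turnover are all modelled against
``tt_cum`` rather than against distance, because it is the time axis on which
bacterial generations accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, OrderingError

__all__ = [
    "Site",
    "Segment",
    "Transect",
    "travel_time",
    "build_transect",
    "discharge_ratio",
    "read_transect_csv",
    "write_transect_csv",
]

#: Optional covariates carried on sites, with their CSV column names.
COVARIATE_COLUMNS = {
    "discharge": "discharge_m3s",
    "temperature": "temperature_c",
    "nitrate": "nitrate_mgl",
    "orthophosphate": "orthophosphate_mgl",
    "doc": "doc_mgl",
    "chlorophyll_a": "chlorophyll_a_ugl",
    "conductivity": "conductivity_uscm",
    "ph": "ph",
    "dissolved_oxygen": "dissolved_oxygen_mgl",
    "tss": "tss_mgl",
    "ecoli": "ecoli_per_100ml",
}


@dataclass
class Site:
    """One sampling site on the river main stem.

    Units: ``rkm`` km from the mouth; ``velocity`` km/h; ``tcc`` cells/l;
    ``bsp`` ugC/l/h; ``mean_cell_volume`` um^3. Covariates are optional and
    missing values propagate as ``None``/NaN.
    """

    site_id: str
    rkm: float
    velocity: float | None = None
    tcc: float | None = None
    bsp: float | None = None
    mean_cell_volume: float | None = None
    discharge: float | None = None
    temperature: float | None = None
    nitrate: float | None = None
    orthophosphate: float | None = None
    doc: float | None = None
    chlorophyll_a: float | None = None
    conductivity: float | None = None
    ph: float | None = None
    dissolved_oxygen: float | None = None
    tss: float | None = None
    ecoli: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rkm < 0:
            raise InvalidInputError(f"site {self.site_id}: rkm must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A river stretch between two adjacent sites (upstream -> downstream)."""

    upstream_site_id: str
    downstream_site_id: str
    distance: float  # km
    mean_velocity: float  # km/h
    tt: float  # hours


@dataclass
class Transect:
    sites: list[Site]
    segments: list[Segment]

    @property
    def tt_cum(self) -> np.ndarray:
        """Cumulative water travel time per site, hours, 0 at the first site."""
        return np.concatenate([[0.0], np.cumsum([s.tt for s in self.segments])])

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def values(self, attr: str) -> np.ndarray:
        """Per-site values of a Site attribute as a float array (NaN = missing)."""
        out = np.empty(len(self.sites))
        for i, s in enumerate(self.sites):
            v = getattr(s, attr)
            out[i] = np.nan if v is None else float(v)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sites):
            row = {
                "site_id": s.site_id,
                "rkm": s.rkm,
                "velocity_kmh": s.velocity,
                "distance_km": np.nan if i == 0 else self.segments[i - 1].distance,
                "tcc_cells_per_l": s.tcc,
                "bsp_ugc_per_l_h": s.bsp,
                "mean_cell_volume_um3": s.mean_cell_volume,
            }
            for attr, col in COVARIATE_COLUMNS.items():
                row[col] = getattr(s, attr)
            row.update(s.extras)
            rows.append(row)
        df = pd.DataFrame(rows)
        df["tt_cum_h"] = self.tt_cum
        return df


def travel_time(distance: float, velocity: float) -> float:
    """Travel time (hours) over ``distance`` km at ``velocity`` km/h."""
    if not (distance > 0):
        raise InvalidInputError("distance must be > 0")
    if not (velocity > 0):
        raise InvalidInputError("velocity must be > 0")
    return distance / velocity


def build_transect(
    sites: Sequence[Site],
    distances: Sequence[float],
    velocity_rule: str = "mean",
) -> Transect:
    """Assemble a :class:`Transect` from ordered sites and inter-site distances.

    Parameters
    ----------
    sites
        Ordered headwater-first, strictly decreasing ``rkm`` (ties are an
        ordering error).
    distances
        One distance (km) per adjacent pair, ``len(sites) - 1`` entries.
    velocity_rule
        ``"mean"`` (default) uses the arithmetic mean of the two endpoint
        velocities for each segment, the least biased choice for monotone
        velocity changes; ``"upstream"`` uses the upstream site's velocity.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise InvalidInputError("a transect needs at least two sites")
    if len(distances) != len(sites) - 1:
        raise InvalidInputError("need exactly one distance per adjacent site pair")
    if velocity_rule not in ("mean", "upstream"):
        raise InvalidInputError(f"unknown velocity_rule {velocity_rule!r}")
    rkms = [s.rkm for s in sites]
    if any(b >= a for a, b in zip(rkms, rkms[1:])):
        raise OrderingError("sites must have strictly decreasing rkm downstream")

    segments = []
    for up, down, dist in zip(sites, sites[1:], distances):
        if up.velocity is None or (velocity_rule == "mean" and down.velocity is None):
            raise InvalidInputError(
                f"segment {up.site_id}->{down.site_id}: missing velocity"
            )
        if velocity_rule == "mean":
            v = 0.5 * (up.velocity + down.velocity)
        else:
            v = up.velocity
        tt = travel_time(dist, v)
        segments.append(
            Segment(
                upstream_site_id=up.site_id,
                downstream_site_id=down.site_id,
                distance=float(dist),
                mean_velocity=float(v),
                tt=tt,
            )
        )
    return Transect(sites=sites, segments=segments)


def discharge_ratio(q, q_min):
    """Discharge normalized to the series minimum at the same location.

    Both arguments may be scalars or arrays; the result is dimensionless and
    >= 1 by construction (the minimum must be the true series minimum).
    """
    q = np.asarray(q, dtype=float)
    q_min = np.asarray(q_min, dtype=float)
    if np.any(q_min <= 0):
        raise InvalidInputError("q_min must be > 0")
    if np.any(q < q_min):
        raise InvalidInputError("q < q_min: q_min must be the series minimum")
    out = q / q_min
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV interface (UTF-8, "." decimal separator)
# ---------------------------------------------------------------------------

def write_transect_csv(transect: Transect, path, meta: str | None = None) -> None:
    df = transect.to_frame().drop(columns=["tt_cum_h"])
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def read_transect_csv(path, velocity_rule: str = "mean") -> Transect:
    """Read the documented transect CSV layout back into a :class:`Transect`.

    Expected columns: ``site_id, rkm, velocity_kmh, distance_km`` plus the
    optional biometry/covariate columns; ``distance_km`` on row *i* is the
    distance from the previous (upstream) site and is ignored on the first row.
    """
    df = pd.read_csv(path, comment="#")
    known = {v: k for k, v in COVARIATE_COLUMNS.items()}
    sites = []
    for _, r in df.iterrows():
        def _get(col):
            v = r.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        extras = {
            c: r[c]
            for c in df.columns
            if c
            not in (
                "site_id",
                "rkm",
                "velocity_kmh",
                "distance_km",
                "tcc_cells_per_l",
                "bsp_ugc_per_l_h",
                "mean_cell_volume_um3",
            )
            and c not in known
        }
        kwargs = {attr: _get(col) for col, attr in known.items()}
        sites.append(
            Site(
                site_id=str(r["site_id"]),
                rkm=float(r["rkm"]),
                velocity=_get("velocity_kmh"),
                tcc=_get("tcc_cells_per_l"),
                bsp=_get("bsp_ugc_per_l_h"),
                mean_cell_volume=_get("mean_cell_volume_um3"),
                extras=extras,
                **kwargs,
            )
        )
    distances = [float(d) for d in df["distance_km"].iloc[1:]]
    return build_transect(sites, distances, velocity_rule=velocity_rule)
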