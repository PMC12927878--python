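"""Phylotype-level growth along the travel-time axis.

Individual ASVs can grow (or wash out) far faster than the bulk community:
their absolute abundances -- relative amplicon abundance times the total
cell count of the sample -- are smoothed against cumulative water travel
time with a penalized cubic regression spline, and the derivative of the
fitted curve estimates the *net* rate of change (production minus loss) at
every point of the transect. The signed extrema of the derivative summarise
each phylotype's strongest bloom and decline; site-to-site log-ratios give a
per-capita rate directly comparable to the bulk division rate.

Smoother implementation: a P-spline (B-spline basis of ``basis_dim`` cubic
functions on an even knot grid, second-order difference penalty on the
coefficients). The penalty weight is chosen by generalized cross-validation
unless a fixed effective df is requested. Pointwise uncertainty bands are
+/- 2 SE from the penalized ("Bayesian") coefficient covariance
``sigma^2 (B'B + lambda S)^{-1}``, an approximate credible envelope; the
derivative band uses the same covariance through the analytic derivative of
the basis. Because the penalty null space contains all straight lines, the
smoother reproduces linear signals exactly and shrinks towards a line (edf
-> 2) as the penalty grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import InvalidInputError
from .production import division_rate  # noqa: F401  (bulk-rate comparisons)

__all__ = [
    "select_asvs",
    "absolute_abundance",
    "SmoothFit",
    "fit_smoother",
    "derivative_series",
    "MaxChange",
    "max_change",
    "sitewise_rate",
    "rate_ratio",
    "growth_table",
]


def select_asvs(
    rel: pd.DataFrame,
    min_ratio: float = 100.0,
    min_max_abund: float = 0.01,
    min_prevalence: int = 20,
    zero_min: str = "pass",
) -> list[str]:
    """Select dynamic phylotypes worth fitting.

    An ASV is retained when it satisfies all three filters on its relative
    abundances (columns of ``rel`` must sum to 1):

    * max/min relative abundance >= ``min_ratio``; with the default
      ``zero_min="pass"`` a zero minimum counts as passing (ratio -> inf),
      the behaviour wanted for bloomers rising from (nearly) zero.
      ``zero_min="pseudo"`` substitutes the smallest positive relative
      abundance representable at the sample depth (1/column total reads is
      not known here, so the smallest positive value in the row is used).
    * maximum relative abundance >= ``min_max_abund`` in at least one sample,
    * present (> 0) in at least ``min_prevalence`` samples.

    Returns the retained ASV ids (possibly empty -- a warning-level event,
    not an error).
    """
    if zero_min not in ("pass", "pseudo"):
        raise InvalidInputError(f"unknown zero_min policy {zero_min!r}")
    colsums = rel.sum(axis=0).to_numpy()
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise InvalidInputError("rel columns must sum to 1")
    keep = []
    for asv, row in rel.iterrows():
        vals = row.to_numpy(dtype=float)
        vmax = vals.max()
        prevalence = int(np.count_nonzero(vals > 0))
        if vmax < min_max_abund or prevalence < min_prevalence:
            continue
        vmin = vals.min()
        if vmin <= 0:
            if zero_min == "pass":
                ratio = math.inf
            else:
                positive = vals[vals > 0]
                ratio = vmax / positive.min() if positive.size else math.inf
        else:
            ratio = vmax / vmin
        if ratio >= min_ratio:
            keep.append(asv)
    return keep


def absolute_abundance(rel, tcc):
    """Absolute phylotype abundance (cells/l) = relative abundance x TCC."""
    rel = np.asarray(rel, dtype=float)
    if np.any(rel < 0) or np.any(rel > 1):
        raise InvalidInputError("relative abundance must lie in [0, 1]")
    tcc = np.asarray(tcc, dtype=float)
    if np.any(tcc <= 0):
        raise InvalidInputError("tcc must be > 0")
    out = rel * tcc
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Penalized spline smoother
# ---------------------------------------------------------------------------

@dataclass
class SmoothFit:
    """A fitted penalized-spline curve with derivative and envelopes."""

    grid: np.ndarray  # strictly increasing travel-time points, hours
    fitted: np.ndarray  # cells/l at grid
    derivative: np.ndarray  # cells/l/h at grid
    band_low: np.ndarray
    band_high: np.ndarray
    deriv_band_low: np.ndarray
    deriv_band_high: np.ndarray
    effective_df: float
    lam: float
    asv_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "asv_id": self.asv_id,
                "tt": self.grid,
                "fitted": self.fitted,
                "deriv": self.derivative,
                "lo": self.band_low,
                "hi": self.band_high,
                "deriv_lo": self.deriv_band_low,
                "deriv_hi": self.deriv_band_high,
            }
        )


def _average_replicates(tt, y):
    """Average observations at identical travel times, return increasing tt."""
    order = np.argsort(tt, kind="stable")
    tt, y = tt[order], y[order]
    uniq, inverse = np.unique(tt, return_inverse=True)
    if len(uniq) == len(tt):
        return tt, y
    sums = np.bincount(inverse, weights=y)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def _basis(tt_min, tt_max, basis_dim, x):
    # Uniform knots extended beyond the data range (classic P-spline setup):
    # with equal knot spacing the Greville abscissae are uniform, so the
    # second-difference penalty's null space is exactly the linear functions
    # and heavy smoothing shrinks towards a straight line rather than
    # distorting it at the boundaries.
    k = 3
    h = (tt_max - tt_min) / (basis_dim - k)
    t = tt_min + (np.arange(basis_dim + k + 1) - k) * h
    xc = np.clip(x, tt_min, tt_max)
    B = BSpline.design_matrix(xc, t, k).toarray()
    return t, B


def _deriv_design(t, basis_dim, x):
    cols = []
    for j in range(basis_dim):
        c = np.zeros(basis_dim)
        c[j] = 1.0
        cols.append(BSpline(t, c, 3).derivative()(x))
    return np.column_stack(cols)


def fit_smoother(
    tt,
    abundance,
    basis_dim: int = 10,
    smooth_selection: str = "gcv",
    fixed_df: float | None = None,
    grid_n: int = 200,
    asv_id: str = "",
) -> SmoothFit:
    """Penalized cubic-spline fit of abundance against travel time.

    Requires at least 8 observations; replicate observations at identical
    travel times are averaged first. The smoothing parameter is selected by
    GCV over a wide log-spaced grid (ties broken towards the smoother fit),
    or, with ``smooth_selection="fixed_df"``, by bisection to match
    ``fixed_df`` effective degrees of freedom. Fitted values, analytic
    derivatives, and +/- 2 SE envelopes are evaluated on a ``grid_n``-point
    uniform grid.
    """
    tt = np.asarray(tt, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if tt.shape != y.shape or tt.ndim != 1:
        raise InvalidInputError("tt and abundance must be equal-length vectors")
    tt, y = _average_replicates(tt, y)
    n = len(tt)
    if n < 8:
        raise InvalidInputError("need at least 8 distinct observations")
    if smooth_selection not in ("gcv", "fixed_df"):
        raise InvalidInputError(f"unknown smooth_selection {smooth_selection!r}")
    basis_dim = int(basis_dim)
    if basis_dim < 4 or basis_dim > n:
        raise InvalidInputError("basis_dim must be between 4 and n")

    t, B = _basis(tt[0], tt[-1], basis_dim, tt)
    D = np.diff(np.eye(basis_dim), n=2, axis=0)
    S = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    # scale-free penalty grid
    scale = np.trace(BtB) / max(np.trace(S), 1e-12)
    lams = scale * np.logspace(-10, 10, 81)

    def _fit(lam):
        A = BtB + lam * S
        coef = np.linalg.solve(A, Bty)
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        rss = float(np.sum((y - B @ coef) ** 2))
        return coef, edf, rss, A

    if smooth_selection == "fixed_df":
        if fixed_df is None or not (2.0 <= fixed_df <= basis_dim):
            raise InvalidInputError("fixed_df must lie in [2, basis_dim]")
        lo, hi = lams[0], lams[-1]
        for _ in range(100):
            mid = math.sqrt(lo * hi)
            _, edf, _, _ = _fit(mid)
            if edf > fixed_df:
                lo = mid
            else:
                hi = mid
        lam = math.sqrt(lo * hi)
    else:
        gcvs = np.empty(len(lams))
        for i, lam_i in enumerate(lams):
            _, edf, rss, _ = _fit(lam_i)
            denom = max(n - edf, 1e-8)
            gcvs[i] = n * rss / denom**2
        best = gcvs.min()
        # break near-ties towards the largest lambda (the smoother fit)
        tol = best * 1e-7 + 1e-12
        lam = float(lams[np.nonzero(gcvs <= best + tol)[0][-1]])

    coef, edf, rss, A = _fit(lam)
    sigma2 = rss / max(n - edf, 1.0)
    Vb = sigma2 * np.linalg.inv(A)  # penalized (Bayesian) covariance

    grid = np.linspace(tt[0], tt[-1], grid_n)
    _, Bg = _basis(tt[0], tt[-1], basis_dim, grid)
    Dg = _deriv_design(t, basis_dim, grid)
    fitted = Bg @ coef
    deriv = Dg @ coef
    se_f = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bg, Vb, Bg), 0.0))
    se_d = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Dg, Vb, Dg), 0.0))
    return SmoothFit(
        grid=grid,
        fitted=fitted,
        derivative=deriv,
        band_low=fitted - 2 * se_f,
        band_high=fitted + 2 * se_f,
        deriv_band_low=deriv - 2 * se_d,
        deriv_band_high=deriv + 2 * se_d,
        effective_df=edf,
        lam=lam,
        asv_id=asv_id,
    )


def derivative_series(fit: SmoothFit) -> pd.DataFrame:
    """The derivative of the fitted curve with its envelope, as a frame.

    The derivative is the analytic derivative of the spline basis (not a
    finite difference), so it integrates back to the fitted net change.
    """
    return pd.DataFrame(
        {
            "tt": fit.grid,
            "deriv": fit.derivative,
            "lo": fit.deriv_band_low,
            "hi": fit.deriv_band_high,
        }
    )


@dataclass(frozen=True)
class MaxChange:
    """Signed extrema of a derivative series over the fitted grid."""

    max_increase: float  # cells/l/h, the largest derivative value
    max_decrease: float  # cells/l/h, the smallest derivative value
    tt_at_max_increase: float
    tt_at_max_decrease: float
    monotone_rising: bool = False  # derivative never negative on the grid
    monotone_falling: bool = False


def max_change(fit: SmoothFit) -> MaxChange:
    d = fit.derivative
    if d.size == 0:
        raise InvalidInputError("empty derivative series")
    i_up = int(np.argmax(d))
    i_dn = int(np.argmin(d))
    return MaxChange(
        max_increase=float(d[i_up]),
        max_decrease=float(d[i_dn]),
        tt_at_max_increase=float(fit.grid[i_up]),
        tt_at_max_decrease=float(fit.grid[i_dn]),
        monotone_rising=bool(np.all(d >= 0)),
        monotone_falling=bool(np.all(d <= 0)),
    )


def sitewise_rate(n_up, n_down, tt):
    """Per-capita net rate (1/day) between two sites from absolute abundances.

    Defined as ``24 * ln(n_down / n_up) / tt`` with ``tt`` in hours: a
    natural-log rate, antisymmetric under swapping the sites. A downstream
    zero is reported as ``-inf`` (washed out below detection); an upstream
    zero is undefined and raises.
    """
    if not (tt > 0):
        raise InvalidInputError("tt must be > 0")
    if n_up is None or not (n_up > 0):
        raise InvalidInputError("n_up must be > 0 (rate undefined from zero)")
    if n_down < 0:
        raise InvalidInputError("n_down must be >= 0")
    if n_down == 0:
        return float("-inf")
    return 24.0 * math.log(n_down / n_up) / tt


def rate_ratio(rate_daily: float, bulk_cd_daily: float) -> float:
    """Ratio of a phylotype per-capita rate to the bulk division rate."""
    if not (bulk_cd_daily > 0):
        raise InvalidInputError("bulk_cd_daily must be > 0")
    return rate_daily / bulk_cd_daily


def growth_table(
    rel: pd.DataFrame,
    tcc: pd.Series,
    tt: pd.Series,
    bulk_cd_daily: float,
    asv_ids: list[str] | None = None,
    basis_dim: int = 10,
) -> pd.DataFrame:
    """Per-ASV growth summary over a transect.

    ``rel`` is the relative-abundance table (columns = samples ordered
    downstream), ``tcc`` and ``tt`` are per-sample total counts and
    cumulative travel times (hours). For each selected ASV the penalized
    spline is fitted to the absolute abundances, and the summary records the
    derivative extrema, their positions, the maximal site-to-site per-capita
    rate, and its ratio to the bulk rate.
    """
    if asv_ids is None:
        asv_ids = select_asvs(rel)
    tt_arr = tt.to_numpy(dtype=float)
    tcc_arr = tcc.to_numpy(dtype=float)
    rows = []
    for asv in asv_ids:
        abund = absolute_abundance(rel.loc[asv].to_numpy(dtype=float), tcc_arr)
        fit = fit_smoother(tt_arr, abund, basis_dim=basis_dim, asv_id=asv)
        mc = max_change(fit)
        best_rate = -math.inf
        for i in range(len(tt_arr) - 1):
            dt = tt_arr[i + 1] - tt_arr[i]
            if dt <= 0 or abund[i] <= 0 or abund[i + 1] <= 0:
                continue
            best_rate = max(best_rate, sitewise_rate(abund[i], abund[i + 1], dt))
        rows.append(
            {
                "asv_id": asv,
                "max_increase": mc.max_increase,
                "max_decrease": mc.max_decrease,
                "peak_tt": mc.tt_at_max_increase,
                "max_sitewise_rate": best_rate,
                "ratio_to_bulk": rate_ratio(best_rate, bulk_cd_daily)
                if math.isfinite(best_rate)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
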