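"""Regression and ordination machinery for transect-scale trends.

Everything here serves one question: how do bulk rates, richness and
community composition change with water travel time (and with the
environmental covariates that fine-tune the hydrological trend)?

* :func:`fit_linear` -- ordinary least squares with slope +/- SE, adjusted
  R^2 and a two-sided t-test p-value, the reporting convention used for all
  simple trend models.
* :func:`backward_select` -- backward elimination over a candidate predictor
  set, by AIC (default) or by a largest-p-above-alpha rule.
* :func:`ordinate` -- principal coordinates (deterministic, default) or
  nonmetric MDS (SMACOF with a PCoA start) of a dissimilarity matrix.
* :func:`vector_fit` -- permutation-based fitting of an environmental
  variable onto ordination axes (the `envfit` idea): R^2 of the variable
  regressed on the axes, with a permutation p-value of (b + 1) / (B + 1).
* :func:`discharge_richness_model` -- richness regressed on log2(discharge
  ratio), so the slope reads "ASVs gained per doubling in discharge".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import as_1d_float, substream
from .errors import (
    DegenerateModelError,
    InvalidInputError,
    RankDeficiencyError,
)

__all__ = [
    "RegressionResult",
    "Ordination",
    "fit_linear",
    "backward_select",
    "ordinate",
    "vector_fit",
    "discharge_richness_model",
]

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """A fitted linear model in the tidy form used for export.

    ``terms`` is indexed by term name (``const`` plus predictors) with
    columns ``estimate``, ``se``, ``p``.
    """

    response_name: str
    predictor_names: list[str]
    terms: pd.DataFrame
    adj_r2: float
    n: int
    aic: float = float("nan")
    model_id: str = ""

    # Conveniences for the single-predictor case -------------------------
    def _single(self):
        if len(self.predictor_names) != 1:
            raise InvalidInputError("slope shortcut needs a single-predictor model")
        return self.predictor_names[0]

    @property
    def slope(self) -> float:
        return float(self.terms.loc[self._single(), "estimate"])

    @property
    def slope_se(self) -> float:
        return float(self.terms.loc[self._single(), "se"])

    @property
    def p_slope(self) -> float:
        return float(self.terms.loc[self._single(), "p"])

    @property
    def intercept(self) -> float:
        return float(self.terms.loc["const", "estimate"])

    def to_tidy(self) -> pd.DataFrame:
        out = self.terms.reset_index(names="term")
        out["adj_r2"] = self.adj_r2
        out["n"] = self.n
        out["model_id"] = self.model_id
        return out


def _drop_missing(y, X: pd.DataFrame):
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("dropped %d observations with missing values (pairwise deletion)",
                 n_dropped)
    return y[mask], X.loc[mask]


def _ols_result(y, X: pd.DataFrame, response_name: str, model_id: str = "") -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    return RegressionResult(
        response_name=response_name,
        predictor_names=list(X.columns),
        terms=terms,
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        aic=float(fit.aic),
        model_id=model_id,
    )


def fit_linear(x, y, x_name: str = "x", y_name: str = "y") -> RegressionResult:
    """Simple OLS of ``y`` on ``x`` with slope +/- SE and adjusted R^2.

    Missing pairs are dropped (and logged); a constant predictor raises a
    degenerate-design error. For a perfect linear fit the SE is 0 and adjusted
    R^2 is 1; adjusted R^2 may be negative for uninformative predictors.
    """
    x = as_1d_float(x, "x")
    y = as_1d_float(y, "y")
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    X = pd.DataFrame({x_name: x})
    y, X = _drop_missing(y, X)
    if len(y) < 3:
        raise InvalidInputError("need at least 3 complete observations")
    if np.ptp(X[x_name].to_numpy()) == 0:
        raise DegenerateModelError(f"predictor {x_name!r} is constant")
    return _ols_result(y, X, y_name, model_id=f"{y_name}~{x_name}")


def backward_select(
    y,
    X: pd.DataFrame,
    criterion: str = "aic",
    alpha: float = 0.05,
) -> RegressionResult:
    """Backward elimination from the full model over candidate predictors.

    ``criterion="aic"`` removes, at each step, the predictor whose removal
    most decreases the AIC, until no removal decreases it.
    ``criterion="alpha"`` removes the predictor with the largest p-value
    above ``alpha`` until all retained predictors are significant at
    ``alpha``. Either way the final (possibly intercept-only) model is
    returned with the retained predictor set.
    """
    if criterion not in ("aic", "alpha"):
        raise InvalidInputError(f"unknown criterion {criterion!r}")
    y = as_1d_float(y, "y")
    X = X.astype(float)
    y, X = _drop_missing(y, X)
    if len(y) <= X.shape[1] + 2:
        raise InvalidInputError("need n > number of candidates + 2")
    design = sm.add_constant(X, has_constant="add").to_numpy()
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offenders = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise RankDeficiencyError(f"collinear predictors: {offenders}")

    kept = list(X.columns)
    current = _ols_result(y, X[kept], "y", model_id="backward")
    while kept:
        if criterion == "aic":
            candidates = []
            for col in kept:
                reduced = [c for c in kept if c != col]
                red_fit = _ols_result(y, X[reduced], "y", model_id="backward")
                candidates.append((red_fit.aic, col, red_fit))
            best_aic, col, red_fit = min(candidates, key=lambda t: t[0])
            if best_aic < current.aic:
                kept.remove(col)
                current = red_fit
                continue
            break
        else:  # alpha rule
            pvals = current.terms.loc[kept, "p"]
            worst = pvals.idxmax()
            if pvals[worst] > alpha:
                kept.remove(worst)
                current = _ols_result(y, X[kept], "y", model_id="backward")
                continue
            break
    return current


@dataclass
class Ordination:
    """Sample coordinates on k ordination axes."""

    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray | None
    method_label: str
    stress: float | None = None
    sample_ids: list[str] | None = None


def _validate_dissimilarity(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidInputError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InvalidInputError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise InvalidInputError("D must have a zero diagonal")
    return D


def _pcoa(D: np.ndarray, k: int):
    """Classical principal coordinates by double-centering + eigh.

    Negative eigenvalues (non-Euclidean dissimilarities) are reported as-is;
    their axes get zero coordinates.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    return coords, evals


def ordinate(
    D,
    k: int = 2,
    method: str = "pcoa",
    seed: int = 0,
    sample_ids: list[str] | None = None,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> Ordination:
    """Ordinate a symmetric dissimilarity matrix on ``k`` axes.

    ``pcoa`` (default) is deterministic and reports the full eigenvalue
    spectrum, negatives included. ``nmds`` runs nonmetric SMACOF stress
    majorization (scikit-learn) started from the PCoA configuration with a
    fixed iteration cap and tolerance.
    """
    D = _validate_dissimilarity(D)
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if method == "pcoa":
        coords, evals = _pcoa(D, k)
        return Ordination(coords, evals, "pcoa", sample_ids=sample_ids)
    if method == "nmds":
        from sklearn.manifold import smacof

        init, _ = _pcoa(D, k)
        if not np.any(D > 0):
            return Ordination(np.zeros((D.shape[0], k)), None, "nmds", stress=0.0,
                              sample_ids=sample_ids)
        coords, stress = smacof(
            D,
            n_components=k,
            metric=False,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=int(seed) & 0x7FFFFFFF,
            normalized_stress=True,
        )
        return Ordination(coords, None, "nmds", stress=float(stress),
                          sample_ids=sample_ids)
    raise InvalidInputError(f"unknown ordination method {method!r}")


def vector_fit(
    ordn: Ordination,
    v,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit an environmental variable onto ordination axes with a permutation test.

    Returns ``(r2, p_perm)`` where ``r2`` is the coefficient of determination
    of ``v`` regressed on the axes and ``p_perm = (#{permuted r2 >= observed}
    + 1) / (permutations + 1)``. Samples with missing ``v`` are dropped
    pairwise (logged).
    """
    v = as_1d_float(v, "v")
    coords = np.asarray(ordn.coordinates, dtype=float)
    if len(v) != coords.shape[0]:
        raise InvalidInputError("v must have one value per ordinated sample")
    mask = np.isfinite(v)
    if not mask.all():
        log.info("vector_fit: dropping %d samples with missing v", int((~mask).sum()))
    v, coords = v[mask], coords[mask]
    if np.ptp(v) == 0:
        raise DegenerateModelError("environmental variable is constant")

    design = np.column_stack([np.ones(len(v)), coords])

    def _r2(resp):
        beta, *_ = np.linalg.lstsq(design, resp, rcond=None)
        resid = resp - design @ beta
        sst = np.sum((resp - resp.mean()) ** 2)
        return 1.0 - np.sum(resid**2) / sst

    obs = _r2(v)
    rng = substream(seed, "vector_fit")
    exceed = 0
    for _ in range(permutations):
        if _r2(rng.permutation(v)) >= obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return float(obs), float(p)


def discharge_richness_model(ratios, richness) -> RegressionResult:
    """Regress richness on log2(discharge ratio).

    The slope is the number of ASVs gained per *doubling* in discharge,
    the only scale-free reading of a per-doubling response. Ratios must be
    >= 1 (normalized to the series minimum beforehand).
    """
    ratios = as_1d_float(ratios, "ratios")
    if np.any(ratios < 1.0 - 1e-12):
        raise InvalidInputError("discharge ratios must be >= 1")
    return fit_linear(np.log2(ratios), as_1d_float(richness, "richness"),
                      x_name="log2_discharge_ratio", y_name="observed_asvs")
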