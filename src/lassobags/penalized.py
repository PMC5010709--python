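"""Penalized stage-1 fits and stage-2 OLS refits.

The lasso solves ``argmin ||y - X b||^2 + lambda ||b||_1``; the adaptive
lasso replaces the penalty by ``lambda sum_j w_j |b_j|`` with per-variable
weights w_j, classically the reciprocal absolute values of an initial
coefficient estimate.  Both are fitted on a geometric lambda grid with
k-fold cross-validation choosing the penalty, via scikit-learn's
coordinate-descent path on the rescaled design (penalize X_j / w_j at a
common lambda, then rescale the coefficients back).

With more covariates than samples the full OLS initial estimate does not
exist; the default weight scheme is therefore per-column (marginal) OLS,
with ridge available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, Ridge, lasso_path
from sklearn.model_selection import KFold

from .containers import Dataset

__all__ = [
    "SelectionResult",
    "FinalModel",
    "initial_weights",
    "fit_lasso",
    "fit_lasso_cv",
    "fit_adaptive_lasso_cv",
    "refit_ols",
    "predict",
]

#: lambda grid: N_GRID geometric points from lambda_max down to
#: GRID_RATIO * lambda_max (glmnet-style path)
N_GRID = 100
GRID_RATIO = 1e-3

_PATH_TOL = 1e-4  # CV passes (fold-level error differences dwarf this)
_FINAL_TOL = 1e-10  # final solve, tight enough for KKT checks


@dataclass
class SelectionResult:
    """Stage-1 selection: the set S of nonzero-coefficient variables.

    ``lambda_`` is on the ``||y - Xb||^2 + lambda ||w b||_1`` scale.
    ``weights`` is aligned with ``var_ids`` (all ones for the plain
    lasso); an infinite weight means the variable was excluded from the
    penalized fit.
    """

    selected: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    weights: np.ndarray
    method: str
    var_ids: list[str]
    cv_lambdas: np.ndarray | None = None
    cv_mse: np.ndarray | None = None

    def coef_map(self) -> dict[str, float]:
        return dict(zip(self.selected, self.coefficients))


@dataclass
class FinalModel:
    """An OLS fit of a named variable set (typically on D2)."""

    variables: list[str]
    coefficients: np.ndarray
    intercept: float
    fit_portion: str = ""
    dropped: list[str] = field(default_factory=list)

    def coef_map(self) -> dict[str, float]:
        return dict(zip(self.variables, self.coefficients))


def initial_weights(
    data: Dataset,
    scheme: str = "lasso_init",
    ridge_alpha: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Adaptive-lasso weights w_j = 1 / |b_init,j|.

    The classical recipe takes the full OLS coefficients as the initial
    estimate, which does not exist for P >= n, so several initial
    estimators are offered:

    * ``lasso_init`` (default) — a cross-validated plain lasso; variables
      it drops get infinite weight, so the adaptive fit refines the
      lasso support (the standard two-step glmnet workflow in high
      dimension);
    * ``marginal_ols`` — univariate OLS per column, always defined;
    * ``ridge`` — L2 fit with penalty ``ridge_alpha``;
    * ``ols`` — full OLS, only for P < n.

    An exactly-zero initial coefficient yields an infinite weight,
    excluding that variable from the penalized fit.
    """
    X, y = data.X, data.y
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if scheme == "lasso_init":
        init = fit_lasso_cv(data, k=k, seed=seed)
        b = np.zeros(p)
        for v, c in init.coef_map().items():
            b[data.column_index(v)] = c
    elif scheme == "marginal_ols":
        ss = np.einsum("ij,ij->j", Xc, Xc)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(ss > 0, Xc.T @ yc / np.where(ss > 0, ss, 1.0), 0.0)
    elif scheme == "ridge":
        b = Ridge(alpha=ridge_alpha, fit_intercept=True).fit(X, y).coef_
    elif scheme == "ols":
        if p >= n:
            raise ValueError(
                f"OLS initial estimate undefined for P={p} >= n={n}; "
                "use scheme='marginal_ols' or 'ridge'"
            )
        b = np.linalg.lstsq(np.column_stack([np.ones(n), Xc]), yc, rcond=None)[0][1:]
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(b)
    return w


def _empty_selection(data: Dataset, weights: np.ndarray, method: str, lam: float = 0.0) -> SelectionResult:
    return SelectionResult(
        selected=[],
        coefficients=np.empty(0),
        intercept=float(np.mean(data.y)),
        lambda_=lam,
        weights=weights,
        method=method,
        var_ids=list(data.var_ids),
    )


def _solve_path(Xc: np.ndarray, yc: np.ndarray, alphas: np.ndarray, tol: float) -> np.ndarray:
    """Coordinate-descent solutions at each alpha (decreasing grid);
    returns coefficients of shape (p, len(alphas))."""
    _, coefs, _ = lasso_path(Xc, yc, alphas=alphas, tol=tol, max_iter=100_000)
    return coefs


def _cv_fit(
    data: Dataset, k: int, seed: int, weights: np.ndarray | None, method: str
) -> SelectionResult:
    X, y = data.X, data.y
    n, p = X.shape
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= n (got k={k}, n={n})")
    if weights is None:
        weights = np.ones(p)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (p,):
        raise ValueError("weights must have one entry per variable")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive (infinite to exclude)")
    keep = np.isfinite(weights)
    if not keep.any():
        warnings.warn("all adaptive weights infinite: empty model")
        return _empty_selection(data, weights, method)

    Xw = X[:, keep] / weights[keep]
    xm = Xw.mean(axis=0)
    ym = float(y.mean())
    Xc = Xw - xm
    yc = y - ym

    alpha_max = float(np.max(np.abs(Xc.T @ yc)) / n)
    if alpha_max <= 0 or not np.isfinite(alpha_max):
        warnings.warn("response carries no signal (constant y): empty model")
        return _empty_selection(data, weights, method)
    alphas = np.geomspace(alpha_max, alpha_max * GRID_RATIO, N_GRID)

    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    cv_err = np.zeros((k, N_GRID))
    for f, (tr, va) in enumerate(folds.split(Xc)):
        xm_tr = Xc[tr].mean(axis=0)
        ym_tr = yc[tr].mean()
        coefs = _solve_path(Xc[tr] - xm_tr, yc[tr] - ym_tr, alphas, _PATH_TOL)
        pred = (Xc[va] - xm_tr) @ coefs + ym_tr
        cv_err[f] = np.mean((yc[va][:, None] - pred) ** 2, axis=0)
    mean_err = cv_err.mean(axis=0)
    # ties broken toward the smallest lambda (grid is decreasing)
    best = int(np.flatnonzero(mean_err == mean_err.min()).max())

    # warm-started path down to the chosen alpha, then a tight final solve
    coefs = _solve_path(Xc, yc, alphas[: best + 1], _PATH_TOL)
    las = Lasso(alpha=alphas[best], fit_intercept=False, tol=_FINAL_TOL,
                max_iter=500_000, warm_start=True)
    las.coef_ = coefs[:, -1].copy()
    las.intercept_ = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        las.fit(Xc, yc)
    beta_keep = las.coef_ / weights[keep]

    beta = np.zeros(p)
    beta[keep] = beta_keep
    nz = np.flatnonzero(beta != 0.0)
    intercept = ym - float(X.mean(axis=0)[nz] @ beta[nz])
    lam = 2.0 * n * alphas[best]
    return SelectionResult(
        selected=[data.var_ids[j] for j in nz],
        coefficients=beta[nz],
        intercept=intercept,
        lambda_=lam,
        weights=weights,
        method=method,
        var_ids=list(data.var_ids),
        cv_lambdas=2.0 * n * alphas,
        cv_mse=mean_err,
    )


def fit_lasso_cv(data: Dataset, k: int = 5, seed: int = 0) -> SelectionResult:
    """Plain lasso with the penalty chosen by k-fold CV (minimum mean
    squared prediction error; ties toward the smaller lambda)."""
    return _cv_fit(data, k, seed, None, "lasso")


def fit_adaptive_lasso_cv(
    data: Dataset, k: int = 5, weights: np.ndarray | None = None, seed: int = 0
) -> SelectionResult:
    """Adaptive lasso via the rescaling identity, penalty by k-fold CV.

    ``weights`` defaults to :func:`initial_weights` with the marginal-OLS
    scheme.
    """
    if weights is None:
        weights = initial_weights(data)
    return _cv_fit(data, k, seed, weights, "adaptive_lasso")


def fit_lasso(
    data: Dataset, lambda_: float, weights: np.ndarray | None = None
) -> SelectionResult:
    """Single (weighted) lasso solve at a fixed penalty, no CV.

    ``lambda_`` is on the ``||y - Xb||^2 + lambda ||w b||_1`` scale;
    ``lambda_=0`` falls back to least squares on the full design.
    """
    X, y = data.X, data.y
    n, p = X.shape
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if weights is None:
        weights = np.ones(p)
    weights = np.asarray(weights, dtype=float)
    keep = np.isfinite(weights)
    Xw = X[:, keep] / weights[keep]
    xm = Xw.mean(axis=0)
    ym = float(y.mean())
    Xc, yc = Xw - xm, y - ym
    if lambda_ == 0:
        bw = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        alpha = lambda_ / (2.0 * n)
        bw = _solve_path(Xc, yc, np.array([alpha]), _FINAL_TOL)[:, 0]
    beta = np.zeros(p)
    beta[keep] = bw / weights[keep]
    nz = np.flatnonzero(beta != 0.0)
    intercept = ym - float(X.mean(axis=0)[nz] @ beta[nz])
    return SelectionResult(
        selected=[data.var_ids[j] for j in nz],
        coefficients=beta[nz],
        intercept=intercept,
        lambda_=float(lambda_),
        weights=weights,
        method="lasso" if np.all(weights[keep] == 1.0) else "adaptive_lasso",
        var_ids=list(data.var_ids),
    )


def _independent_columns(A: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns
    (earlier columns win), via incremental Gram-Schmidt."""
    n = A.shape[0]
    Q: list[np.ndarray] = []
    keep = []
    for j in range(A.shape[1]):
        v = A[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        for qcol in Q:
            v = v - (qcol @ A[:, j]) * qcol
        # re-orthogonalize once for numerical safety
        for qcol in Q:
            v = v - (qcol @ v) * qcol
        nv = np.linalg.norm(v)
        if norm0 > 0 and nv > tol * max(1.0, norm0) and len(Q) < n:
            Q.append(v / nv)
            keep.append(j)
    return keep


def refit_ols(variables: list[str], data: Dataset, fit_portion: str = "") -> FinalModel:
    """Ordinary least squares of y on the named columns plus an intercept.

    Rank-deficient designs are handled by dropping later-listed collinear
    columns with a warning; dropped ids are recorded on the model.
    """
    variables = list(variables)
    n = data.n
    if len(variables) >= n:
        raise ValueError(f"{len(variables)} variables but only {n} rows: OLS ill-posed")
    if not variables:
        return FinalModel([], np.empty(0), float(np.mean(data.y)), fit_portion)
    A = np.column_stack([np.ones(n), data.columns(variables)])
    keep = _independent_columns(A)
    if 0 not in keep:  # intercept always first and nonzero
        keep = [0] + keep
    dropped = [variables[j - 1] for j in range(1, A.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping collinear columns from OLS refit: {dropped}")
    kept_vars = [variables[j - 1] for j in keep if j > 0]
    Ak = A[:, keep]
    coef = np.linalg.lstsq(Ak, data.y, rcond=None)[0]
    return FinalModel(kept_vars, coef[1:], float(coef[0]), fit_portion, dropped)


def predict(model: FinalModel, data: Dataset) -> np.ndarray:
    """Linear predictions of a fitted model on (possibly different) data."""
    missing = [v for v in model.variables if v not in set(data.var_ids)]
    if missing:
        raise KeyError(f"variables absent from data: {missing}")
    if not model.variables:
        return np.full(data.n, model.intercept)
    return model.intercept + data.columns(model.variables) @ model.coefficients
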