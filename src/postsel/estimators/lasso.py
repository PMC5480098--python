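"""L1 path estimators: LASSO, least-angle regression, relaxed LASSO."""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import lasso_path, lars_path

from .base import (TuningGrid, PenalizedFit, make_folds, lambda_grid,
                   cv_loss_linear, cv_loss_logistic)
from ._solver import enet_path_solver

__all__ = ["fit_lasso", "fit_lars", "fit_relaxed_lasso"]


def _center(X, y):
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def _linear_lasso_path(X, y, lams):
    """Coefficients (L, p) and intercepts (L,) of the lasso path."""
    Xc, yc, xm, ym = _center(X, y)
    _, coefs, _ = lasso_path(Xc, yc, alphas=lams)
    B = coefs.T
    b0s = ym - B @ xm
    return B, b0s


def fit_lasso(X, y, family: str, grid: TuningGrid | None = None) -> PenalizedFit:
    """LASSO with lambda chosen by fivefold CV (minimum-CV rule).

    Objective: (negative log-likelihood)/n + lambda * ||beta||_1 with an
    unpenalized intercept; the linear path goes through scikit-learn, the
    logistic path through the package's coordinate-descent solver.
    """
    grid = grid or TuningGrid()
    n = X.shape[0]
    lams = lambda_grid(X, y, grid)
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    cv = np.zeros(len(lams))
    for train, test in folds:
        if family == "linear":
            B, b0s = _linear_lasso_path(X[train], y[train], lams)
            pred = X[test] @ B.T + b0s
            cv += cv_loss_linear(y[test], pred)
        else:
            B, b0s = enet_path_solver(X[train], y[train], "logistic", lams)
            eta = X[test] @ B.T + b0s
            cv += cv_loss_logistic(y[test], eta)
    k = int(np.argmin(cv))
    if family == "linear":
        B, b0s = _linear_lasso_path(X, y, lams)
    else:
        B, b0s = enet_path_solver(X, y, "logistic", lams)
    return PenalizedFit(
        method="lasso", family=family, intercept=float(b0s[k]),
        beta=B[k].copy(),
        tuning={"lambda": float(lams[k]), "lambda_index": k},
        diagnostics={"cv_curve": (cv / grid.cv_folds).tolist(),
                     "lambda_grid": lams.tolist()},
    )


def _lar_coefs_at_step(coefs: np.ndarray, k: int) -> np.ndarray:
    """Column k of the (p, K) LAR coefficient path, clamped to the last step."""
    return coefs[:, min(k, coefs.shape[1] - 1)]


def fit_lars(X, y, grid: TuningGrid | None = None) -> PenalizedFit:
    """Least-angle regression (LAR, without the lasso modification).

    CV selects the number of path steps; the support is the active set at
    that step of the full-data path.
    """
    grid = grid or TuningGrid()
    n, p = X.shape
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    max_steps = min(p, n - 1)
    cv = np.zeros(max_steps + 1)
    for train, test in folds:
        Xc, yc, xm, ym = _center(X[train], y[train])
        _, _, coefs = lars_path(Xc, yc, method="lar", max_iter=max_steps)
        for k in range(max_steps + 1):
            b = _lar_coefs_at_step(coefs, k)
            pred = ym + (X[test] - xm) @ b
            cv[k] += cv_loss_linear(y[test], pred)
    k = int(np.argmin(cv))
    Xc, yc, xm, ym = _center(X, y)
    _, active, coefs = lars_path(Xc, yc, method="lar", max_iter=max_steps)
    beta = _lar_coefs_at_step(coefs, k).copy()
    early_stop = coefs.shape[1] - 1 < max_steps
    return PenalizedFit(
        method="lars", family="linear",
        intercept=float(ym - beta @ xm), beta=beta,
        tuning={"step": k},
        diagnostics={"cv_curve": (cv / grid.cv_folds).tolist(),
                     "path_steps": coefs.shape[1] - 1,
                     "early_stop": bool(early_stop)},
    )


def _relaxed_betas(Xc, yc, B1, lams, phis):
    """Stage-2 coefficient array (L, n_phi, p) for a whole lasso path.

    Stage-1 supports repeat along the path, so work is grouped by unique
    support; within a group each phi's sub-path is warm-started.
    """
    from ._solver import fit_gaussian

    L, p = B1.shape
    out = np.zeros((L, len(phis), p))
    groups: dict[tuple, list[int]] = {}
    for i in range(L):
        key = tuple(np.flatnonzero(np.abs(B1[i]) > 1e-12))
        groups.setdefault(key, []).append(i)
    for key, idxs in groups.items():
        s = np.asarray(key, int)
        if s.size == 0:
            continue
        Xs = Xc[:, s]
        bs_ols = None
        for j, phi in enumerate(phis):
            if phi == 1.0:
                for i in idxs:
                    out[i, j] = B1[i]
            elif phi == 0.0:
                if bs_ols is None:
                    bs_ols, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
                for i in idxs:
                    out[i, j, s] = bs_ols
            else:
                warm = None
                for i in idxs:  # lams descending along the path
                    warm, _ = fit_gaussian(Xs, yc, phi * lams[i], 0.0,
                                           beta=warm, fit_intercept=False)
                    out[i, j, s] = warm
    return out


def fit_relaxed_lasso(X, y, grid: TuningGrid | None = None) -> PenalizedFit:
    """Two-stage relaxed LASSO, CV over (lambda, phi).

    Stage 1 selects a support with the LASSO at lambda; stage 2 refits the
    LASSO restricted to that support with the weaker penalty phi*lambda
    (phi = 0 is an unpenalized refit, phi = 1 recovers the plain LASSO).
    """
    grid = grid or TuningGrid()
    n = X.shape[0]
    lams = lambda_grid(X, y, grid)
    phis = tuple(grid.phis)
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    cv = np.zeros((len(lams), len(phis)))
    for train, test in folds:
        Xc, yc, xm, ym = _center(X[train], y[train])
        Xc1 = X[train] - xm  # stage-1 path uses the same centering
        _, coefs, _ = lasso_path(Xc1, yc, alphas=lams)
        B1 = coefs.T
        B2 = _relaxed_betas(Xc1, yc, B1, lams, phis)
        Xt = X[test] - xm
        for j in range(len(phis)):
            pred = ym + Xt @ B2[:, j, :].T
            cv[:, j] += cv_loss_linear(y[test], pred)
    i, j = np.unravel_index(int(np.argmin(cv)), cv.shape)
    lam, phi = float(lams[i]), float(phis[j])
    Xc, yc, xm, ym = _center(X, y)
    _, coefs, _ = lasso_path(Xc, yc, alphas=lams)
    B1 = coefs.T
    support = np.flatnonzero(np.abs(B1[i]) > 1e-12)
    beta = _relaxed_betas(Xc, yc, B1[i:i + 1], lams[i:i + 1], (phi,))[0, 0]
    empty = support.size == 0
    return PenalizedFit(
        method="relaxo", family="linear",
        intercept=float(ym - beta @ xm), beta=beta,
        tuning={"lambda": lam, "phi": phi},
        diagnostics={"empty_support": bool(empty),
                     "cv_min": float(cv[i, j] / grid.cv_folds)},
    )
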