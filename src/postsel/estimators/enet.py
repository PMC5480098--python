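"""Elastic net and combined L1/L2 penalized GLM estimators.

The elastic net here is the *corrected* (rescaled) form: the naive
solution of ``(1/2n)||y - X b||^2 + lam1 ||b||_1 + (lam2/2) ||b||_2^2``
multiplied by ``(1 + lam2)``, which undoes the double shrinkage of
stacking an L1 on top of a ridge penalty.  The whole L1 path at a fixed
lam2 is the lasso path of a ridge-augmented design, computed exactly by
LARS; cross-validation runs over the ridge grid and the L1 arc-length
fraction ``s in [0, 1]`` of the path.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import lars_path

from .base import (TuningGrid, PenalizedFit, make_folds, lambda_grid,
                   cv_loss_linear, cv_loss_logistic)
from ._solver import fit_gaussian, fit_logistic, newton_logistic
from .lasso import fit_lasso, _center

__all__ = ["fit_elastic_net", "fit_penalized_glm", "lars_en_path",
           "path_at_fractions"]


def lars_en_path(X, y, lam2, max_steps=500):
    """Exact corrected elastic-net path at a fixed ridge penalty.

    Returns ``(coefs, xm, ym)``: the (p, K) coefficient path on the
    corrected scale for centered data, plus the centering used.  With
    ``lam2 = 0`` this is the plain lasso path.
    """
    n, p = X.shape
    xm, ym = X.mean(axis=0), float(y.mean())
    Xc, yc = X - xm, y - ym
    if lam2 > 0:
        Xa = np.vstack([Xc, np.sqrt(n * lam2) * np.eye(p)])
        ya = np.concatenate([yc, np.zeros(p)])
    else:
        Xa, ya = Xc, yc
    _, _, coefs = lars_path(Xa, ya, method="lasso", max_iter=max_steps)
    return coefs * (1.0 + lam2), xm, ym


def path_at_fractions(coefs: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Path coefficients at L1 arc-length fractions of the final norm.

    The LARS path is piecewise linear in its coefficients, so linear
    interpolation between breakpoints is exact.
    """
    norms = np.abs(coefs).sum(axis=0)
    mx = norms[-1] if norms[-1] > 0 else 1.0
    s = norms / mx
    out = np.empty((coefs.shape[0], len(fractions)))
    for i, t in enumerate(fractions):
        k = int(np.searchsorted(s, t))
        if k <= 0:
            out[:, i] = coefs[:, 0]
        elif k >= len(s):
            out[:, i] = coefs[:, -1]
        else:
            w = (t - s[k - 1]) / max(s[k] - s[k - 1], 1e-12)
            out[:, i] = (1 - w) * coefs[:, k - 1] + w * coefs[:, k]
    return out


def fit_elastic_net(X, y, family: str = "linear",
                    grid: TuningGrid | None = None) -> PenalizedFit:
    """Corrected elastic net, CV over (ridge penalty, L1 fraction)."""
    if family != "linear":
        raise ValueError("the elastic-net path estimator is linear-family "
                         "only; use fit_penalized_glm for logistic L1/L2")
    grid = grid or TuningGrid()
    n = X.shape[0]
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    lam2s = tuple(grid.enet_lambda2)
    fractions = np.linspace(0.0, 1.0, grid.enet_n_fractions)
    cv = np.zeros((len(lam2s), len(fractions)))
    for train, test in folds:
        for k2, lam2 in enumerate(lam2s):
            coefs, xm, ym = lars_en_path(X[train], y[train], lam2)
            B = path_at_fractions(coefs, fractions)      # (p, S)
            pred = ym + (X[test] - xm) @ B
            cv[k2] += cv_loss_linear(y[test], pred)
    k2, ks = np.unravel_index(int(np.argmin(cv)), cv.shape)
    lam2, frac = float(lam2s[k2]), float(fractions[ks])
    coefs, xm, ym = lars_en_path(X, y, lam2)
    beta = path_at_fractions(coefs, np.array([frac]))[:, 0]
    return PenalizedFit(
        method="enet", family="linear",
        intercept=float(ym - beta @ xm), beta=beta,
        tuning={"lambda2": lam2, "fraction": frac},
        diagnostics={"cv_min": float(cv[k2, ks] / grid.cv_folds)},
    )


def _fit_ridge(X, y, family: str, grid: TuningGrid) -> PenalizedFit:
    """Pure-L2 penalized GLM, lambda by CV; no coefficient is zeroed."""
    n, p = X.shape
    lams = np.asarray(grid.ridge_lambdas, float)
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    cv = np.zeros(len(lams))
    for train, test in folds:
        for k, lam in enumerate(lams):
            if family == "linear":
                b, b0 = fit_gaussian(X[train], y[train], 0.0, lam)
                cv[k] += cv_loss_linear(y[test], X[test] @ b + b0)
            else:
                b, b0, _ = newton_logistic(X[train], y[train], lam)
                cv[k] += cv_loss_logistic(y[test], X[test] @ b + b0)
    k = int(np.argmin(cv))
    if family == "linear":
        beta, b0 = fit_gaussian(X, y, 0.0, lams[k])
    else:
        beta, b0, _ = newton_logistic(X, y, lams[k])
    return PenalizedFit(
        method="penalized", family=family, intercept=float(b0), beta=beta,
        tuning={"lambda2": float(lams[k])},
        diagnostics={"pure_ridge": True},
    )


def _penalty_path(X, y, family, lams, lam2):
    """L1 path at a fixed absolute ridge penalty ``lam2``."""
    if family == "linear" and lam2 == 0.0:
        from .lasso import _linear_lasso_path
        return _linear_lasso_path(X, y, lams)
    n, p = X.shape
    B = np.empty((len(lams), p))
    b0s = np.empty(len(lams))
    beta, b0 = np.zeros(p), None
    for k, lam in enumerate(lams):
        if family == "linear":
            beta, b0 = fit_gaussian(X, y, lam, lam2, beta=beta,
                                    b0=0.0 if b0 is None else b0)
        else:
            beta, b0, _ = fit_logistic(X, y, lam, lam2, beta=beta, b0=b0,
                                       tol=1e-6)
        B[k], b0s[k] = beta, b0
    return B, b0s


def fit_penalized_glm(X, y, family: str, grid: TuningGrid | None = None,
                      l1: bool = True, l2: bool = True) -> PenalizedFit:
    """Penalized likelihood with L1, L2, or both.

    The combination profiles an L1 path against each value of a small
    absolute ridge grid (``grid.lambda2_grid``) and CVs jointly over
    (lambda1, lambda2); pure-L1 reduces to the LASSO and pure-L2 to a
    CV-tuned ridge fit.
    """
    grid = grid or TuningGrid()
    if not l1 and not l2:
        raise ValueError("at least one of l1, l2 must be enabled")
    if l1 and not l2:
        fit = fit_lasso(X, y, family, grid)
        fit.method = "penalized"
        return fit
    if l2 and not l1:
        return _fit_ridge(X, y, family, grid)
    n = X.shape[0]
    lams = lambda_grid(X, y, grid)
    lam2s = tuple(grid.lambda2_grid)
    folds = make_folds(n, grid.cv_folds, grid.fold_seed)
    cv = np.zeros((len(lam2s), len(lams)))
    loss = cv_loss_linear if family == "linear" else cv_loss_logistic
    for train, test in folds:
        for k2, lam2 in enumerate(lam2s):
            B, b0s = _penalty_path(X[train], y[train], family, lams, lam2)
            cv[k2] += loss(y[test], X[test] @ B.T + b0s)
    k2, k1 = np.unravel_index(int(np.argmin(cv)), cv.shape)
    B, b0s = _penalty_path(X, y, family, lams, lam2s[k2])
    return PenalizedFit(
        method="penalized", family=family, intercept=float(b0s[k1]),
        beta=B[k1].copy(),
        tuning={"lambda1": float(lams[k1]), "lambda2": float(lam2s[k2])},
        diagnostics={"cv_min": float(cv[k2, k1] / grid.cv_folds)},
    )
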