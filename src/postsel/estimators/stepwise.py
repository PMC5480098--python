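"""Forward stepwise L2-penalized logistic regression (BIC-type stopping).

At each step the Rao score statistic (computed from the current ridge
fit) ranks the candidate predictors; the best candidate is added if it
lowers the penalized-deviance-plus-BIC score

    score(S) = deviance(ridge fit on S) + log(n) * (|S| + 1).

The ridge penalty is chosen once by fivefold CV on the full model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .base import TuningGrid, PenalizedFit, make_folds, cv_loss_logistic
from ._solver import newton_logistic, logistic_deviance

__all__ = ["fit_stepwise_ridge_logistic"]


def _cv_ridge_lambda(X, y, grid: TuningGrid) -> float:
    folds = make_folds(X.shape[0], grid.cv_folds, grid.fold_seed)
    lams = np.asarray(grid.ridge_lambdas, float)
    cv = np.zeros(len(lams))
    for train, test in folds:
        for k, lam in enumerate(lams):
            b, b0, _ = newton_logistic(X[train], y[train], lam)
            cv[k] += cv_loss_logistic(y[test], X[test] @ b + b0)
    return float(lams[int(np.argmin(cv))])


def _score_statistics(X, y, support, mu, w):
    """Rao score statistic for adding each non-member, given fitted probs."""
    n, p = X.shape
    resid = y - mu
    Z = np.column_stack([np.ones(n), X[:, support]]) if True else None
    WZ = Z * w[:, None]
    G = Z.T @ WZ                      # (k+1, k+1)
    Ginv_ZtW = np.linalg.solve(G, WZ.T)   # (k+1, n)
    stats = np.full(p, -np.inf)
    mask = np.ones(p, bool)
    mask[support] = False
    Xc = X[:, mask]
    u = Xc.T @ resid                              # score
    WX = Xc * w[:, None]
    diag_full = np.einsum("ij,ij->j", Xc, WX)     # x' W x
    proj = Z.T @ WX                               # (k+1, m)
    corr = np.einsum("kj,kj->j", proj, np.linalg.solve(G, proj))
    var = np.maximum(diag_full - corr, 1e-12)
    stats[mask] = u * u / var
    return stats


def fit_stepwise_ridge_logistic(X, y, grid: TuningGrid | None = None) -> PenalizedFit:
    grid = grid or TuningGrid()
    n, p = X.shape
    lam2 = _cv_ridge_lambda(X, y, grid)
    support: list[int] = []
    # intercept-only start
    pbar = min(max(y.mean(), 1e-8), 1 - 1e-8)
    b0 = float(np.log(pbar / (1 - pbar)))
    beta_s = np.zeros(0)
    eta = np.full(n, b0)
    score = logistic_deviance(y, eta) + np.log(n) * 1
    score_path = [score]
    max_size = min(p, n - 2)
    while len(support) < max_size:
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-5)
        stats = _score_statistics(X, y, np.asarray(support, int), mu, w)
        j = int(np.argmax(stats))
        if not np.isfinite(stats[j]):
            break
        trial = support + [j]
        warm = np.append(beta_s, 0.0)
        b_try, b0_try, _ = newton_logistic(X[:, trial], y, lam2,
                                           beta=warm, b0=b0)
        eta_try = b0_try + X[:, trial] @ b_try
        score_try = logistic_deviance(y, eta_try) + np.log(n) * (len(trial) + 1)
        if score_try < score - 1e-8:
            support, beta_s, b0, eta, score = trial, b_try, b0_try, eta_try, score_try
            score_path.append(score)
        else:
            break
    beta = np.zeros(p)
    beta[support] = beta_s
    return PenalizedFit(
        method="stepplr", family="logistic", intercept=b0, beta=beta,
        tuning={"lambda2": lam2},
        diagnostics={"score_path": score_path, "n_steps": len(support),
                     "selection_order": list(support)},
    )
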