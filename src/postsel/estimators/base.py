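"""Shared infrastructure for the selection estimators.

All estimators share one tuning convention: a geometric lambda path from
the data-driven ``lambda_max`` down to ``lambda_min_ratio * lambda_max``,
fivefold cross-validation with the minimum-CV rule, squared-error loss
for the linear family and mean binomial deviance for the logistic family.
Fold assignment depends only on ``(n, fold_seed)`` so that every method
sees identical folds within a replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["TuningGrid", "PenalizedFit", "make_folds", "lambda_grid",
           "cv_loss_linear", "cv_loss_logistic", "ZERO_TOL"]

#: coefficients with absolute value at or below this are reported as zero
ZERO_TOL = 1e-8


@dataclass(frozen=True)
class TuningGrid:
    """Cross-validation grids shared by all estimators.

    ``enet_lambda2`` is the elastic net's ridge grid and
    ``enet_n_fractions`` the size of its L1-fraction grid on [0, 1];
    ``phis`` is the relaxed-LASSO relaxation grid (0 = unpenalized
    refit); ``scad_a`` the SCAD concavity constant; ``ridge_lambdas`` the
    L2 grid for the stepwise ridge-logistic method and ``lambda2_grid``
    the ridge grid of the combined-penalty GLM (all penalties on the
    per-observation loss scale).
    """

    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    enet_lambda2: tuple = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
    enet_n_fractions: int = 21
    phis: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    scad_a: float = 3.7
    ridge_lambdas: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    lambda2_grid: tuple = (0.01, 0.1, 1.0)
    cv_folds: int = 5
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("need at least two lambda values")
        if self.scad_a <= 2:
            raise ValueError("SCAD concavity a must exceed 2")
        if any(not 0.0 <= phi <= 1.0 for phi in self.phis):
            raise ValueError("relaxation phi must lie in [0, 1]")


@dataclass
class PenalizedFit:
    """A fitted selection estimator: full-length coefficients and support."""

    method: str
    family: str
    intercept: float
    beta: np.ndarray
    tuning: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    zero_tol: float = ZERO_TOL

    @property
    def support(self) -> np.ndarray:
        """Zero-based indices of coefficients deemed nonzero."""
        return np.flatnonzero(np.abs(self.beta) > self.zero_tol)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "family": self.family,
            "intercept": float(self.intercept), "beta": self.beta.tolist(),
            "support": self.support.tolist(), "tuning": self.tuning,
            "diagnostics": self.diagnostics,
        }


def make_folds(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic k-fold split depending only on ``(n, k, seed)``."""
    order = np.random.default_rng(seed).permutation(n)
    parts = np.array_split(order, k)
    folds = []
    for i in range(k):
        test = np.sort(parts[i])
        train = np.sort(np.concatenate([parts[j] for j in range(k) if j != i]))
        folds.append((train, test))
    return folds


def lambda_grid(X: np.ndarray, y: np.ndarray, grid: TuningGrid,
                alpha: float = 1.0) -> np.ndarray:
    """Geometric lambda path from the null-model entry threshold down.

    ``lambda_max = max_j |x_j'(y - ybar)| / (n * alpha)`` is the smallest
    penalty at which all slopes are zero (for the logistic family ``ybar``
    is the intercept-only fitted probability, so the same formula applies
    with ``y - ybar`` the null-model residual).
    """
    n = X.shape[0]
    r = y - y.mean()
    lam_max = np.max(np.abs(X.T @ r)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * grid.lambda_min_ratio, grid.n_lambda)


def cv_loss_linear(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Mean squared error; ``yhat`` may be (n,) or (n, L)."""
    d = yhat - (y[:, None] if yhat.ndim == 2 else y)
    return np.mean(d * d, axis=0)


def cv_loss_logistic(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Mean binomial deviance at linear predictor ``eta`` ((n,) or (n, L))."""
    yy = y[:, None] if eta.ndim == 2 else y
    # 2 * [log(1 + e^eta) - y*eta], written stably
    return 2.0 * np.mean(np.logaddexp(0.0, eta) - yy * eta, axis=0)
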