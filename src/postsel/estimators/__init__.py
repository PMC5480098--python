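"""Selection estimators behind a single registry interface.

Registered methods (``METHODS``):

========== =========================================== ==================
name       description                                 families
========== =========================================== ==================
lasso      L1-penalized regression                     linear, logistic
lars       least-angle regression (LAR path)           linear
enet       corrected elastic net (LARS-EN path)        linear
relaxo     relaxed LASSO (two-stage, CV over phi)      linear
scad       one-step SCAD (local linear approximation)  linear, logistic
penalized  GLM with combined L1/L2 penalty             linear, logistic
stepplr    forward stepwise ridge logistic (BIC stop)  logistic
========== =========================================== ==================
"""

from __future__ import annotations

from .base import TuningGrid, PenalizedFit, make_folds, lambda_grid, ZERO_TOL
from .lasso import fit_lasso, fit_lars, fit_relaxed_lasso
from .enet import fit_elastic_net, fit_penalized_glm
from .scad import fit_scad, scad_derivative
from .stepwise import fit_stepwise_ridge_logistic

__all__ = [
    "TuningGrid", "PenalizedFit", "make_folds", "lambda_grid", "ZERO_TOL",
    "fit_lasso", "fit_lars", "fit_relaxed_lasso", "fit_elastic_net",
    "fit_penalized_glm", "fit_scad", "scad_derivative",
    "fit_stepwise_ridge_logistic", "METHODS", "fit_method",
]

#: method name -> (fit callable accepting (X, y, family, grid), families)
METHODS = {
    "lasso": (lambda X, y, family, grid: fit_lasso(X, y, family, grid),
              ("linear", "logistic")),
    "lars": (lambda X, y, family, grid: fit_lars(X, y, grid),
             ("linear",)),
    "enet": (lambda X, y, family, grid: fit_elastic_net(X, y, family, grid),
             ("linear",)),
    "relaxo": (lambda X, y, family, grid: fit_relaxed_lasso(X, y, grid),
               ("linear",)),
    "scad": (lambda X, y, family, grid: fit_scad(X, y, family, grid),
             ("linear", "logistic")),
    "penalized": (lambda X, y, family, grid: fit_penalized_glm(X, y, family, grid),
                  ("linear", "logistic")),
    "stepplr": (lambda X, y, family, grid: fit_stepwise_ridge_logistic(X, y, grid),
                ("logistic",)),
}


def fit_method(name: str, X, y, family: str,
               grid: TuningGrid | None = None) -> PenalizedFit:
    """Fit a registered method; raises for unknown names or wrong family."""
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; available: {sorted(METHODS)}")
    fn, families = METHODS[name]
    if family not in families:
        raise ValueError(f"method {name!r} supports families {families}, "
                         f"not {family!r}")
    return fn(X, y, family, grid or TuningGrid())
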