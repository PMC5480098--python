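"""Post-selection inference: adaptive (plug-in) and oracle (refit) algorithms.

Both algorithms operate on the selected design ``X_S = [1, X_j : j in S]``
where ``S`` is the support of a penalized fit.

* Adaptive: keep the penalized point estimates and plug them into the
  usual covariance formula — linear: ``sigma2_adapt (X_S' X_S)^{-1}`` with
  ``sigma2_adapt`` the mean squared error of the penalized fit on
  ``n - p_adapt`` degrees of freedom; logistic:
  ``(X_S' V_adapt X_S)^{-1}`` with ``V_adapt`` the Bernoulli variances at
  the penalized estimates.
* Oracle: refit an unpenalized model on ``X_S`` (least squares /
  logistic MLE) and use its standard covariance.

``p_adapt`` counts the intercept.  Wald intervals use the normal quantile.
Degenerate replicates (p_adapt >= n, singular selected design, perfect
separation) are flagged rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SelectedInference", "select_design",
    "adaptive_inference_linear", "oracle_inference_linear",
    "adaptive_inference_logistic", "oracle_inference_logistic",
    "confidence_intervals",
]

_COND_WARN = 1e12
_PROB_CLIP = 1e-10


@dataclass
class SelectedInference:
    """Point estimates, covariance and Wald CIs on the selected design."""

    algorithm: str                   # "adapt" | "oracle"
    family: str
    indices: np.ndarray              # selected predictor indices (0-based)
    estimates: np.ndarray            # length p_adapt, intercept first
    cov: np.ndarray | None
    sigma2: float | None = None      # linear families only
    level: float | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    degenerate: bool = False
    flags: dict = field(default_factory=dict)

    @property
    def p_adapt(self) -> int:
        return len(self.estimates)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm, "family": self.family,
            "indices": self.indices.tolist(),
            "estimates": self.estimates.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "sigma2": self.sigma2, "level": self.level,
            "lower": None if self.lower is None else self.lower.tolist(),
            "upper": None if self.upper is None else self.upper.tolist(),
            "degenerate": self.degenerate, "flags": self.flags,
        }


def select_design(X: np.ndarray, fit) -> tuple[np.ndarray, np.ndarray]:
    """Selected design ``[1, X_j for j in support]`` (columns index-ordered)."""
    idx = np.asarray(fit.support, dtype=int)
    XS = np.column_stack([np.ones(X.shape[0]), X[:, idx]])
    return XS, idx


def _degenerate(algorithm, family, idx, estimates, reason) -> SelectedInference:
    inf = SelectedInference(
        algorithm=algorithm, family=family, indices=idx,
        estimates=estimates, cov=None, degenerate=True,
        flags={"reason": reason},
    )
    confidence_intervals(inf)
    return inf


def _stable_inverse(M: np.ndarray, flags: dict) -> np.ndarray | None:
    """Symmetric PD inverse via Cholesky; None when singular."""
    try:
        c, low = sla.cho_factor(M)
    except (sla.LinAlgError, ValueError):
        return None
    cond = np.linalg.cond(M)
    if cond > _COND_WARN:
        flags["ill_conditioned"] = float(cond)
    inv = sla.cho_solve((c, low), np.eye(M.shape[0]))
    return (inv + inv.T) / 2.0


def adaptive_inference_linear(XS, y, beta_adapt, idx=None, level=0.95):
    """Algorithm 1 (linear): penalized estimates, plug-in covariance."""
    n, pa = XS.shape
    idx = np.arange(pa - 1) if idx is None else np.asarray(idx, int)
    beta_adapt = np.asarray(beta_adapt, float)
    if pa >= n:
        return _degenerate("adapt", "linear", idx, beta_adapt, "p_adapt >= n")
    resid = y - XS @ beta_adapt
    sigma2 = float(resid @ resid) / (n - pa)
    flags: dict = {}
    inv = _stable_inverse(XS.T @ XS, flags)
    if inv is None:
        return _degenerate("adapt", "linear", idx, beta_adapt, "singular design")
    inf = SelectedInference("adapt", "linear", idx, beta_adapt,
                            cov=sigma2 * inv, sigma2=sigma2, flags=flags)
    confidence_intervals(inf, level)
    return inf


def oracle_inference_linear(XS, y, idx=None, level=0.95):
    """Algorithm 2 (linear): least-squares refit on the selected design."""
    n, pa = XS.shape
    idx = np.arange(pa - 1) if idx is None else np.asarray(idx, int)
    if pa >= n:
        return _degenerate("oracle", "linear", idx, np.full(pa, np.nan),
                           "p_adapt >= n")
    beta, _, rank, _ = np.linalg.lstsq(XS, y, rcond=None)
    if rank < pa:
        return _degenerate("oracle", "linear", idx, beta, "rank-deficient design")
    resid = y - XS @ beta
    sigma2 = float(resid @ resid) / (n - pa)
    flags: dict = {}
    inv = _stable_inverse(XS.T @ XS, flags)
    if inv is None:
        return _degenerate("oracle", "linear", idx, beta, "singular design")
    inf = SelectedInference("oracle", "linear", idx, beta,
                            cov=sigma2 * inv, sigma2=sigma2, flags=flags)
    confidence_intervals(inf, level)
    return inf


def _logistic_cov(XS, eta, flags):
    mu = expit(eta)
    clipped = bool(np.any(mu < _PROB_CLIP) or np.any(mu > 1 - _PROB_CLIP))
    if clipped:
        mu = np.clip(mu, _PROB_CLIP, 1 - _PROB_CLIP)
        flags["probabilities_clipped"] = True
    V = mu * (1 - mu)
    return _stable_inverse(XS.T @ (XS * V[:, None]), flags)


def adaptive_inference_logistic(XS, y, beta_adapt, idx=None, level=0.95):
    """Algorithm 1 (logistic): Fisher information at the penalized estimates."""
    n, pa = XS.shape
    idx = np.arange(pa - 1) if idx is None else np.asarray(idx, int)
    beta_adapt = np.asarray(beta_adapt, float)
    if pa >= n:
        return _degenerate("adapt", "logistic", idx, beta_adapt, "p_adapt >= n")
    flags: dict = {}
    cov = _logistic_cov(XS, XS @ beta_adapt, flags)
    if cov is None:
        return _degenerate("adapt", "logistic", idx, beta_adapt, "singular information")
    inf = SelectedInference("adapt", "logistic", idx, beta_adapt, cov=cov,
                            flags=flags)
    confidence_intervals(inf, level)
    return inf


def oracle_inference_logistic(XS, y, idx=None, level=0.95):
    """Algorithm 2 (logistic): unpenalized MLE refit on the selected design.

    Complete or quasi-complete separation is flagged as degenerate (the
    MLE diverges); such replicates are tallied, not silently dropped.
    """
    n, pa = XS.shape
    idx = np.arange(pa - 1) if idx is None else np.asarray(idx, int)
    if pa >= n:
        return _degenerate("oracle", "logistic", idx, np.full(pa, np.nan),
                           "p_adapt >= n")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, XS, family=sm.families.Binomial()).fit(maxiter=100)
        beta = np.asarray(res.params, float)
    except Exception as exc:  # separation / singular design
        return _degenerate("oracle", "logistic", idx, np.full(pa, np.nan),
                           f"refit failed: {type(exc).__name__}")
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30.0:
        return _degenerate("oracle", "logistic", idx, beta, "separation")
    flags: dict = {}
    cov = _logistic_cov(XS, XS @ beta, flags)
    if cov is None:
        return _degenerate("oracle", "logistic", idx, beta, "singular information")
    if np.max(np.diag(cov)) > 1e4:  # exploding SEs: quasi-separation
        return _degenerate("oracle", "logistic", idx, beta, "separation")
    inf = SelectedInference("oracle", "logistic", idx, beta, cov=cov,
                            flags=flags)
    confidence_intervals(inf, level)
    return inf


def confidence_intervals(inf: SelectedInference, level: float = 0.95):
    """Wald intervals ``estimate +- z_{(1+level)/2} * sqrt(cov_jj)``."""
    if inf.degenerate or inf.cov is None:
        inf.level = level
        inf.lower = inf.upper = np.full(inf.p_adapt, np.nan)
        return inf.lower, inf.upper
    z = norm.ppf((1 + level) / 2)
    se = np.sqrt(np.clip(np.diag(inf.cov), 0.0, None))
    inf.level = level
    inf.lower = inf.estimates - z * se
    inf.upper = inf.estimates + z * se
    return inf.lower, inf.upper
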