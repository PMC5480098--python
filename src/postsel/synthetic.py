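"""Synthetic data generation for the selection-inference study.

The generating truth is a sparse coefficient vector over ``p`` predictors
of which only the first ``p_star`` carry signal, all with a common
magnitude, half positive and half negative.  Predictors are multivariate
normal with identity, block-exchangeable, or lag-truncated autoregressive
correlation, or independent Bernoulli(0.5).  Outcomes are either

* linear: ``y = beta0 + X beta + eps`` with N(0, 1) or Student-t errors, or
* logistic case-control: population draws of ``Y ~ Bern(expit(beta0 + X beta))``
  retained until exactly ``n1`` cases and ``n0`` controls are collected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CorrelationSpec", "TrueModel", "SimulatedDataset",
    "build_correlation", "build_coefficients", "make_true_model",
    "simulate_linear", "simulate_case_control", "save_dataset", "load_dataset",
]

#: hard cap on population draws for one case-control dataset
CASE_CONTROL_DRAW_CAP = 1_000_000


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation structure of the multivariate-normal predictors.

    kind
        ``identity``, ``block`` (disjoint exchangeable blocks of
        ``block_size`` with off-diagonal ``rho``), or ``ar``
        (``rho**|i-j|`` truncated to zero beyond ``max_lag``).
    """

    kind: str
    p: int
    rho: float = 0.5
    block_size: int = 5
    max_lag: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "block", "ar"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


@dataclass(frozen=True)
class TrueModel:
    """The data-generating truth: family, sparse coefficients, error law."""

    family: str                      # "linear" | "logistic"
    p: int
    p_star: int
    beta: np.ndarray                 # full length-p vector (zeros beyond support)
    beta0: float = 0.0
    error_kind: str = "normal"       # "normal" | "t2" | "t15"  (linear only)
    sigma2: float = 1.0
    predictor_kind: str = "mvnormal"  # "mvnormal" | "binary"

    @property
    def support(self) -> np.ndarray:
        """Zero-based indices of the truly associated predictors."""
        return np.flatnonzero(self.beta != 0.0)

    @property
    def beta_star(self) -> np.ndarray:
        return self.beta[: self.p_star]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = self.beta.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        d = dict(d)
        d["beta"] = np.asarray(d["beta"], dtype=float)
        return cls(**d)


@dataclass
class SimulatedDataset:
    """One replicate: design matrix, outcome, and provenance."""

    X: np.ndarray
    y: np.ndarray
    seed: int | None = None
    n0: int | None = None            # case-control counts (logistic only)
    n1: int | None = None
    design: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_correlation(spec: CorrelationSpec, repair: bool = False) -> np.ndarray:
    """Build the predictor correlation matrix and verify positive definiteness.

    With ``repair=True`` a non-PD matrix (possible for aggressive lag
    truncation) is projected onto the nearest PSD matrix by eigenvalue
    clipping and renormalised to unit diagonal; by default it is an error.
    """
    p, rho = spec.p, spec.rho
    if spec.kind == "identity":
        sigma = np.eye(p)
    elif spec.kind == "block":
        sigma = np.eye(p)
        for start in range(0, p, spec.block_size):
            stop = min(start + spec.block_size, p)
            sigma[start:stop, start:stop] = rho
        np.fill_diagonal(sigma, 1.0)
    else:  # ar
        lags = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        sigma = np.where(lags <= spec.max_lag, rho ** lags.astype(float), 0.0)
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin <= 1e-10:
        if not repair:
            raise np.linalg.LinAlgError(
                f"correlation matrix not positive definite (lambda_min={eigmin:.3g}); "
                "pass repair=True to project to the nearest PD matrix"
            )
        w, v = np.linalg.eigh(sigma)
        sigma = (v * np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def build_coefficients(p: int, p_star: int, magnitude: float) -> np.ndarray:
    """Length-p coefficient vector: first ``p_star`` entries ``+/-magnitude``.

    The first half of the support is positive, the second half negative
    (a fixed convention; selection and coverage metrics are symmetric in
    sign).  The remaining ``p - p_star`` entries are exactly zero.
    """
    if p_star > p:
        raise ValueError("p_star cannot exceed p")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    beta = np.zeros(p)
    n_pos = (p_star + 1) // 2
    beta[:n_pos] = magnitude
    beta[n_pos:p_star] = -magnitude
    return beta


def make_true_model(
    family: str,
    p: int = 50,
    p_star: int = 10,
    magnitude: float = 0.5,
    beta0: float | None = None,
    error_kind: str = "normal",
    predictor_kind: str = "mvnormal",
) -> TrueModel:
    """Convenience constructor for the study's generating models.

    The logistic intercept defaults to -1 (the population prevalence used
    throughout the case-control designs); the linear intercept defaults
    to 0.
    """
    if beta0 is None:
        beta0 = -1.0 if family == "logistic" else 0.0
    return TrueModel(
        family=family, p=p, p_star=p_star,
        beta=build_coefficients(p, p_star, magnitude),
        beta0=beta0, error_kind=error_kind, predictor_kind=predictor_kind,
    )


def _draw_X(rng: np.random.Generator, n: int, model: TrueModel,
            chol: np.ndarray | None) -> np.ndarray:
    if model.predictor_kind == "binary":
        return (rng.random((n, model.p)) < 0.5).astype(float)
    return rng.standard_normal((n, model.p)) @ chol.T


def _chol_for(model: TrueModel, corr: CorrelationSpec | np.ndarray | None) -> np.ndarray | None:
    if model.predictor_kind == "binary":
        return None
    if corr is None:
        corr = CorrelationSpec("identity", model.p)
    sigma = build_correlation(corr) if isinstance(corr, CorrelationSpec) else np.asarray(corr)
    return np.linalg.cholesky(sigma)


def simulate_linear(
    model: TrueModel,
    corr: CorrelationSpec | np.ndarray | None,
    n: int,
    seed: int,
) -> SimulatedDataset:
    """Draw one linear-model replicate ``y = beta0 + X beta + eps``.

    Errors are N(0, sigma2) for ``error_kind='normal'`` or unscaled
    Student t with 2 or 15 df (the heavy-tail robustness violations;
    t(2) has no finite variance so no variance standardisation exists).
    """
    if model.family != "linear":
        raise ValueError("simulate_linear requires a linear-family TrueModel")
    rng = np.random.default_rng(seed)
    X = _draw_X(rng, n, model, _chol_for(model, corr))
    if model.error_kind == "normal":
        eps = rng.standard_normal(n) * np.sqrt(model.sigma2)
    elif model.error_kind == "t2":
        eps = rng.standard_t(2, n)
    elif model.error_kind == "t15":
        eps = rng.standard_t(15, n)
    else:
        raise ValueError(f"unknown error_kind {model.error_kind!r}")
    y = model.beta0 + X @ model.beta + eps
    return SimulatedDataset(X=X, y=y, seed=seed,
                            design={"model": model.to_dict(), "n": n})


def simulate_case_control(
    model: TrueModel,
    corr: CorrelationSpec | np.ndarray | None,
    n0: int,
    n1: int,
    seed: int,
    batch: int = 4096,
) -> SimulatedDataset:
    """Draw a case-control sample with exactly ``n1`` cases and ``n0`` controls.

    Population units ``(X, Y)`` with ``Y ~ Bernoulli(expit(beta0 + X beta))``
    are generated in batches; units are retained in draw order until each
    arm's quota is filled.  A cap on total population draws guards against
    degenerate configurations where one arm is essentially never observed.
    """
    if model.family != "logistic":
        raise ValueError("simulate_case_control requires a logistic-family TrueModel")
    rng = np.random.default_rng(seed)
    chol = _chol_for(model, corr)
    rows0, rows1 = [], []
    k0 = k1 = 0
    drawn = 0
    while k0 < n0 or k1 < n1:
        if drawn >= CASE_CONTROL_DRAW_CAP:
            raise RuntimeError(
                f"case-control sampling exceeded the {CASE_CONTROL_DRAW_CAP} "
                f"population-draw cap (collected {k1}/{n1} cases, {k0}/{n0} controls)"
            )
        m = min(batch, CASE_CONTROL_DRAW_CAP - drawn)
        Xb = _draw_X(rng, m, model, chol)
        yb = rng.random(m) < expit(model.beta0 + Xb @ model.beta)
        drawn += m
        if k1 < n1:
            take = Xb[yb][: n1 - k1]
            rows1.append(take)
            k1 += take.shape[0]
        if k0 < n0:
            take = Xb[~yb][: n0 - k0]
            rows0.append(take)
            k0 += take.shape[0]
    X = np.vstack([np.vstack(rows1) if rows1 else np.empty((0, model.p)),
                   np.vstack(rows0) if rows0 else np.empty((0, model.p))])
    y = np.r_[np.ones(n1), np.zeros(n0)]
    return SimulatedDataset(X=X, y=y, seed=seed, n0=n0, n1=n1,
                            design={"model": model.to_dict(), "n0": n0, "n1": n1})


def save_dataset(ds: SimulatedDataset, csv_path: str | Path) -> None:
    """Write ``x1..xp,y`` CSV plus a JSON sidecar with truth and seed."""
    csv_path = Path(csv_path)
    cols = {f"x{j + 1}": ds.X[:, j] for j in range(ds.p)}
    cols["y"] = ds.y
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {"seed": ds.seed, "n0": ds.n0, "n1": ds.n1, "design": ds.design}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(csv_path: str | Path) -> SimulatedDataset:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    xcols = [c for c in df.columns if c != "y"]
    return SimulatedDataset(
        X=df[xcols].to_numpy(float), y=df["y"].to_numpy(float),
        seed=meta.get("seed"), n0=meta.get("n0"), n1=meta.get("n1"),
        design=meta.get("design", {}),
    )
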