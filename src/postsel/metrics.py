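"""Performance criteria: FP/FN selection rates and CI coverage.

All rates follow the same averaging order: a per-coefficient rate over
replicates first, then the mean over the relevant coefficient set
(true zeros for FP and null-coverage, true signals for FN,
signal-coverage and truth-coverage).

Coverage of zero counts a coefficient as covered when it is either
dropped by the selection (estimate exactly zero, no CI needed) or its CI
contains zero.  Coverage of the truth is conditional on selection: only
(replicate, coefficient) pairs with a nonzero estimate enter; the
unconditional variant (dividing by all replicates) is available behind a
flag for sensitivity analysis.  Replicates flagged degenerate for an
algorithm are excluded from that algorithm's coverage numerators and
denominators but tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateOutcome", "MetricsRow", "fp_rate", "fn_rate",
    "coverage_of_zero", "coverage_of_truth", "aggregate", "outcomes_to_frame",
]


@dataclass
class ReplicateOutcome:
    """Per-replicate record of selection and CI events for both algorithms."""

    beta_true: np.ndarray            # length p
    selected: np.ndarray             # bool length p
    ci_adapt: np.ndarray             # (p, 2), NaN where not selected
    ci_oracle: np.ndarray            # (p, 2)
    degenerate_adapt: bool = False
    degenerate_oracle: bool = False
    failed: bool = False             # estimator crashed; no events recorded

    def __post_init__(self):
        p = len(self.beta_true)
        if not (len(self.selected) == p and self.ci_adapt.shape == (p, 2)
                and self.ci_oracle.shape == (p, 2)):
            raise ValueError("misaligned outcome arrays")


@dataclass
class MetricsRow:
    """One results-table row: a (design cell, method) summary."""

    method: str
    family: str
    fp: float
    fn: float
    cov_zero_null_adapt: float
    cov_zero_null_oracle: float
    cov_zero_signal_adapt: float
    cov_zero_signal_oracle: float
    cov_truth_adapt: float
    cov_truth_oracle: float
    n_reps: int
    n_analysed: int
    n_degenerate_adapt: int
    n_degenerate_oracle: int
    n_failed: int
    cell_failed: bool = False
    design: dict = field(default_factory=dict)

    #: fixed column order mirroring the results tables
    COLUMNS = (
        "method", "family", "corr", "n", "beta", "error", "predictors",
        "fp", "fn",
        "cov_zero_null_adapt", "cov_zero_null_oracle",
        "cov_zero_signal_adapt", "cov_zero_signal_oracle",
        "cov_truth_adapt", "cov_truth_oracle",
        "n_reps", "n_analysed", "n_degenerate_adapt", "n_degenerate_oracle",
        "n_failed", "cell_failed",
    )

    def to_record(self) -> dict:
        d = asdict(self)
        design = d.pop("design")
        rec = {
            "corr": design.get("corr"), "n": design.get("n"),
            "beta": design.get("beta"), "error": design.get("error"),
            "predictors": design.get("predictors"),
        }
        rec.update(d)
        return {c: rec.get(c) for c in self.COLUMNS}


def _usable(outcomes):
    out = [o for o in outcomes if not o.failed]
    if not out:
        raise ValueError("no analysable replicates")
    return out


def _selection_rate(outcomes, over_zeros: bool) -> float:
    out = _usable(outcomes)
    beta = out[0].beta_true
    mask = beta == 0 if over_zeros else beta != 0
    if not mask.any():
        raise ValueError("no coefficients in the requested set")
    sel = np.array([o.selected for o in out])
    per_coef = sel[:, mask].mean(axis=0)
    if over_zeros:
        return float(per_coef.mean())
    return float((1.0 - per_coef).mean())


def fp_rate(outcomes) -> float:
    """Fraction of truly-zero coefficients estimated nonzero (per-coefficient
    rate over replicates, averaged over the zero coefficients)."""
    return _selection_rate(outcomes, over_zeros=True)


def fn_rate(outcomes) -> float:
    """Mirror of :func:`fp_rate` over the truly-nonzero coefficients."""
    out = _usable(outcomes)
    beta = out[0].beta_true
    if not (beta != 0).any():
        raise ValueError("no nonzero coefficients")
    sel = np.array([o.selected for o in out])
    per_coef = sel[:, beta != 0].mean(axis=0)
    return float((1.0 - per_coef).mean())


def _ci_stack(outcomes, algorithm):
    if algorithm == "adapt":
        ok = [o for o in outcomes if not o.degenerate_adapt]
        cis = np.array([o.ci_adapt for o in ok]) if ok else np.empty((0,))
    elif algorithm == "oracle":
        ok = [o for o in outcomes if not o.degenerate_oracle]
        cis = np.array([o.ci_oracle for o in ok]) if ok else np.empty((0,))
    else:
        raise ValueError("algorithm must be 'adapt' or 'oracle'")
    return ok, cis


def coverage_of_zero(outcomes, which: str, algorithm: str) -> float:
    """Coverage of zero for true zeros (``which='null'``) or true signals
    (``which='signal'``): dropped, or CI contains zero."""
    out = _usable(outcomes)
    beta = out[0].beta_true
    if which == "null":
        mask = beta == 0
    elif which == "signal":
        mask = beta != 0
    else:
        raise ValueError("which must be 'null' or 'signal'")
    if not mask.any():
        raise ValueError("no coefficients in the requested set")
    ok, cis = _ci_stack(out, algorithm)
    if not ok:
        return float("nan")
    sel = np.array([o.selected for o in ok])[:, mask]
    lo, hi = cis[:, mask, 0], cis[:, mask, 1]
    contains0 = (lo <= 0.0) & (hi >= 0.0)
    covered = np.where(sel, contains0, True)
    return float(covered.mean(axis=0).mean())


def coverage_of_truth(outcomes, algorithm: str,
                      conditional: bool = True) -> float:
    """CI coverage of the true signal values, conditional on selection.

    Per signal coefficient: among (non-degenerate) replicates where it was
    selected, the fraction whose CI contains the true value; averaged over
    the signal coefficients.  A coefficient never selected contributes no
    term (logged).  ``conditional=False`` divides by all replicates
    instead, conflating non-selection with non-coverage.
    """
    out = _usable(outcomes)
    beta = out[0].beta_true
    mask = beta != 0
    if not mask.any():
        raise ValueError("no nonzero coefficients")
    ok, cis = _ci_stack(out, algorithm)
    if not ok:
        return float("nan")
    sel = np.array([o.selected for o in ok])[:, mask]
    lo, hi = cis[:, mask, 0], cis[:, mask, 1]
    truth = beta[mask]
    hit = sel & (lo <= truth) & (truth <= hi)
    n_sel = sel.sum(axis=0)
    if conditional:
        defined = n_sel > 0
        if not defined.all():
            warnings.warn(
                f"{int((~defined).sum())} signal coefficient(s) never selected; "
                "excluded from coverage-of-truth", stacklevel=2)
        if not defined.any():
            return float("nan")
        per_coef = hit.sum(axis=0)[defined] / n_sel[defined]
    else:
        per_coef = hit.mean(axis=0)
    return float(per_coef.mean())


def aggregate(outcomes, method: str, family: str,
              design: dict | None = None) -> MetricsRow:
    """Assemble one results-table row from per-replicate outcomes."""
    if not outcomes:
        raise ValueError("empty outcome list")
    n_reps = len(outcomes)
    n_failed = sum(o.failed for o in outcomes)
    analysable = [o for o in outcomes if not o.failed]
    cell_failed = n_failed > 0.5 * n_reps
    if cell_failed or not analysable:
        nan = float("nan")
        return MetricsRow(method, family, nan, nan, nan, nan, nan, nan, nan,
                          nan, n_reps, 0, 0, 0, n_failed, True, design or {})
    return MetricsRow(
        method=method, family=family,
        fp=fp_rate(analysable), fn=fn_rate(analysable),
        cov_zero_null_adapt=coverage_of_zero(analysable, "null", "adapt"),
        cov_zero_null_oracle=coverage_of_zero(analysable, "null", "oracle"),
        cov_zero_signal_adapt=coverage_of_zero(analysable, "signal", "adapt"),
        cov_zero_signal_oracle=coverage_of_zero(analysable, "signal", "oracle"),
        cov_truth_adapt=coverage_of_truth(analysable, "adapt"),
        cov_truth_oracle=coverage_of_truth(analysable, "oracle"),
        n_reps=n_reps, n_analysed=len(analysable),
        n_degenerate_adapt=sum(o.degenerate_adapt for o in analysable),
        n_degenerate_oracle=sum(o.degenerate_oracle for o in analysable),
        n_failed=n_failed, cell_failed=False, design=design or {},
    )


def outcomes_to_frame(outcomes) -> pd.DataFrame:
    """Long-format audit event log: one row per (replicate, coefficient)."""
    rows = []
    for r, o in enumerate(outcomes):
        if o.failed:
            continue
        for j in range(len(o.beta_true)):
            rows.append({
                "replicate": r, "coef": j,
                "beta_true": o.beta_true[j], "selected": bool(o.selected[j]),
                "lo_adapt": o.ci_adapt[j, 0], "hi_adapt": o.ci_adapt[j, 1],
                "lo_oracle": o.ci_oracle[j, 0], "hi_oracle": o.ci_oracle[j, 1],
                "degenerate_adapt": o.degenerate_adapt,
                "degenerate_oracle": o.degenerate_oracle,
            })
    return pd.DataFrame(rows)
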