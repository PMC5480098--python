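"""Simulation harness: factorial grids of (method, design) cells.

One *cell* is a (design, method) pair run for R replicates.  Seeding is
hierarchical and order-invariant: replicate r of a cell derives its data
and fold seeds from ``SeedSequence((master_seed, cell_key_crc, r))``, so
any single replicate is exactly reproducible and results do not depend
on execution order (replicates are safe to parallelize).
"""

from __future__ import annotations

import json
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .synthetic import CorrelationSpec, make_true_model, simulate_linear, simulate_case_control
from .estimators import TuningGrid, fit_method, METHODS
from .inference import (select_design, adaptive_inference_linear,
                        oracle_inference_linear, adaptive_inference_logistic,
                        oracle_inference_logistic)
from .metrics import ReplicateOutcome, MetricsRow, aggregate

__all__ = ["SimulationDesign", "ResultsTable", "run_replicate", "run_cell",
           "run_grid", "run_pgt_n", "paper_grid", "PGTN_METHODS"]

#: methods that remain usable when p > n (the others fail routinely there)
PGTN_METHODS = ("lasso", "lars", "relaxo")


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the factorial simulation grid."""

    family: str                       # "linear" | "logistic"
    corr_kind: str = "identity"       # identity | block | ar (mvnormal only)
    predictor_kind: str = "mvnormal"  # mvnormal | binary
    n: int = 100                      # linear sample size
    n0: int | None = None             # case-control counts (logistic)
    n1: int | None = None
    p: int = 50
    p_star: int = 10
    magnitude: float = 0.5
    error_kind: str = "normal"
    beta0: float | None = None        # None -> family default (0 / -1)
    ci_level: float = 0.95

    def true_model(self):
        return make_true_model(self.family, p=self.p, p_star=self.p_star,
                               magnitude=self.magnitude, beta0=self.beta0,
                               error_kind=self.error_kind,
                               predictor_kind=self.predictor_kind)

    def correlation(self) -> CorrelationSpec | None:
        if self.predictor_kind == "binary":
            return None
        return CorrelationSpec(self.corr_kind, self.p)

    def key(self, method: str) -> str:
        n_part = f"n{self.n}" if self.family == "linear" else f"n0{self.n0}n1{self.n1}"
        return (f"{method}|{self.family}|{self.corr_kind}|{self.predictor_kind}|"
                f"{n_part}|p{self.p}|ps{self.p_star}|b{self.magnitude}|"
                f"{self.error_kind}")

    def describe(self) -> dict:
        n = self.n if self.family == "linear" else self.n0
        return {"corr": self.corr_kind if self.predictor_kind == "mvnormal" else "-",
                "n": n, "beta": self.magnitude, "error": self.error_kind,
                "predictors": self.predictor_kind}


@dataclass
class ResultsTable:
    rows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_record() for r in self.rows],
                            columns=list(MetricsRow.COLUMNS))

    def to_csv(self, path) -> None:
        # %.17g keeps float round-trips bit-exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _replicate_seeds(master_seed: int, cell_key: str, r: int):
    crc = zlib.crc32(cell_key.encode())
    state = np.random.SeedSequence((master_seed, crc, r)).generate_state(2)
    return int(state[0] & 0x7FFFFFFF), int(state[1] & 0x7FFFFFFF)


def run_replicate(design: SimulationDesign, method: str, data_seed: int,
                  fold_seed: int, grid: TuningGrid) -> ReplicateOutcome:
    """Simulate one dataset, fit the method, run both inference algorithms."""
    model = design.true_model()
    corr = design.correlation()
    if design.family == "linear":
        ds = simulate_linear(model, corr, design.n, data_seed)
    else:
        ds = simulate_case_control(model, corr, design.n0, design.n1, data_seed)
    grid_r = replace(grid, fold_seed=fold_seed)
    p = design.p
    nanci = np.full((p, 2), np.nan)
    try:
        fit = fit_method(method, ds.X, ds.y, design.family, grid_r)
    except Exception:
        return ReplicateOutcome(model.beta, np.zeros(p, bool), nanci.copy(),
                                nanci.copy(), failed=True)
    XS, idx = select_design(ds.X, fit)
    beta_adapt = np.r_[fit.intercept, fit.beta[idx]]
    if design.family == "linear":
        inf_a = adaptive_inference_linear(XS, ds.y, beta_adapt, idx,
                                          design.ci_level)
        inf_o = oracle_inference_linear(XS, ds.y, idx, design.ci_level)
    else:
        inf_a = adaptive_inference_logistic(XS, ds.y, beta_adapt, idx,
                                            design.ci_level)
        inf_o = oracle_inference_logistic(XS, ds.y, idx, design.ci_level)
    selected = np.zeros(p, bool)
    selected[idx] = True
    ci_a, ci_o = nanci.copy(), nanci.copy()
    if not inf_a.degenerate:
        ci_a[idx, 0] = inf_a.lower[1:]
        ci_a[idx, 1] = inf_a.upper[1:]
    if not inf_o.degenerate:
        ci_o[idx, 0] = inf_o.lower[1:]
        ci_o[idx, 1] = inf_o.upper[1:]
    return ReplicateOutcome(model.beta, selected, ci_a, ci_o,
                            degenerate_adapt=inf_a.degenerate,
                            degenerate_oracle=inf_o.degenerate)


def run_cell(design: SimulationDesign, method: str, reps: int, seed: int,
             grid: TuningGrid | None = None, n_jobs: int = 1,
             return_outcomes: bool = False):
    """Run one (design, method) cell; returns a :class:`MetricsRow`.

    A cell whose estimator fails in more than half the replicates is
    marked failed (rates NaN) rather than reported from the survivors.
    """
    if method not in METHODS:
        raise KeyError(f"unknown method {method!r}")
    grid = grid or TuningGrid()
    key = design.key(method)
    seeds = [_replicate_seeds(seed, key, r) for r in range(reps)]
    if n_jobs == 1:
        outcomes = [run_replicate(design, method, ds_, fs_, grid)
                    for ds_, fs_ in seeds]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(design, method, ds_, fs_, grid)
            for ds_, fs_ in seeds)
    row = aggregate(outcomes, method, design.family, design.describe())
    if return_outcomes:
        return row, outcomes
    return row


def run_grid(designs, methods, reps: int, seed: int,
             grid: TuningGrid | None = None, out_dir=None,
             resume: bool = False, n_jobs: int = 1,
             progress: bool = True) -> ResultsTable:
    """Map :func:`run_cell` over designs x methods, writing incrementally.

    With ``resume=True`` cells already present in ``out_dir/results.csv``
    are skipped; identical seeds make the resumed table equal the
    uninterrupted one.
    """
    grid = grid or TuningGrid()
    out_path = None
    done_keys: set[str] = set()
    rows: list[MetricsRow] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "results.csv"
        if resume and out_path.exists():
            prev = pd.read_csv(out_path)
            done_keys = set(prev["cell_key"])
        elif out_path.exists():
            out_path.unlink()
    t0 = time.time()
    for design in designs:
        for method in methods:
            families = METHODS[method][1]
            if design.family not in families:
                continue
            key = design.key(method)
            if key in done_keys:
                continue
            row = run_cell(design, method, reps, seed, grid, n_jobs=n_jobs)
            rows.append(row)
            if progress:
                print(f"[{time.time() - t0:8.1f}s] {key}: fp={row.fp:.3f} "
                      f"fn={row.fn:.3f}", file=sys.stderr)
            if out_path is not None:
                rec = row.to_record()
                rec["cell_key"] = key
                pd.DataFrame([rec]).to_csv(out_path, mode="a", index=False,
                                           header=not out_path.exists())
    table = ResultsTable(rows, meta={"seed": seed, "reps": reps,
                                     "grid": asdict(grid)})
    if out_dir is not None:
        (Path(out_dir) / "meta.json").write_text(json.dumps(table.meta, indent=1))
    return table


def run_pgt_n(design: SimulationDesign, method: str, reps: int, seed: int,
              grid: TuningGrid | None = None, allow_ridge_init_scad: bool = False,
              n_jobs: int = 1, return_outcomes: bool = False):
    """High-dimensional (p > n) variant; only the path methods that remain
    stable there are allowed (ridge-initialized SCAD behind a flag)."""
    allowed = set(PGTN_METHODS) | ({"scad"} if allow_ridge_init_scad else set())
    if method not in allowed:
        raise ValueError(
            f"method {method!r} is not run for p > n designs (allowed: "
            f"{sorted(allowed)}); it fails too often in this regime")
    return run_cell(design, method, reps, seed, grid, n_jobs=n_jobs,
                    return_outcomes=return_outcomes)


def paper_grid(family: str, magnitudes=(0.25, 0.5, 1.0),
               sample_sizes=(100, 200, 500)) -> list[SimulationDesign]:
    """The full factorial study grid for one outcome family.

    Linear: 3 correlation structures x 3 sample sizes x 3 magnitudes.
    Logistic: {normal-identity, binary} predictors x 3 case-control sizes
    x 3 magnitudes, with equal case and control counts.
    """
    designs = []
    if family == "linear":
        for corr in ("identity", "block", "ar"):
            for n in sample_sizes:
                for b in magnitudes:
                    designs.append(SimulationDesign(
                        family="linear", corr_kind=corr, n=n, magnitude=b))
    elif family == "logistic":
        for pk in ("mvnormal", "binary"):
            for n in sample_sizes:
                for b in magnitudes:
                    designs.append(SimulationDesign(
                        family="logistic", corr_kind="identity",
                        predictor_kind=pk, n0=n, n1=n, magnitude=b))
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    return designs
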