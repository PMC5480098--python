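"""Selection-rate and coverage metrics, including the audit-log recount."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from postsel.metrics import (ReplicateOutcome, fp_rate, fn_rate,
                             coverage_of_zero, coverage_of_truth, aggregate,
                             outcomes_to_frame, MetricsRow)


def _outcome(beta_true, beta_hat, ci_adapt=None, ci_oracle=None, **kw):
    beta_true = np.asarray(beta_true, float)
    beta_hat = np.asarray(beta_hat, float)
    p = len(beta_true)
    nan = np.full((p, 2), np.nan)
    sel = beta_hat != 0
    ca = nan.copy() if ci_adapt is None else np.asarray(ci_adapt, float)
    co = nan.copy() if ci_oracle is None else np.asarray(ci_oracle, float)
    return ReplicateOutcome(beta_true, sel, ca, co, **kw)


def _random_outcomes(rng, R=50, p=6):
    beta = np.array([1.0, -1.0, 0.5, 0, 0, 0])
    outs = []
    for _ in range(R):
        sel = rng.random(p) < 0.6
        ci_a = np.full((p, 2), np.nan)
        ci_o = np.full((p, 2), np.nan)
        for j in np.flatnonzero(sel):
            ca = np.sort(rng.normal(beta[j], 1.0, 2))
            co = np.sort(rng.normal(beta[j], 0.7, 2))
            ci_a[j], ci_o[j] = ca, co
        outs.append(ReplicateOutcome(beta, sel, ci_a, ci_o,
                                     degenerate_adapt=rng.random() < 0.1,
                                     degenerate_oracle=rng.random() < 0.1))
    return outs


class TestRates:
    def test_fp_definitional(self):
        outs = [_outcome([1, 0, 0], [0.5, 0.2, 0.0])]
        assert fp_rate(outs) == 0.5

    def test_fp_everything_selected(self):
        outs = [_outcome([1, 0, 0], [1, 1, 1])] * 3
        assert fp_rate(outs) == 1.0

    def test_fn_definitional(self):
        outs = [_outcome([1, -1], [0.0, -1.0])]
        assert fn_rate(outs) == 0.5

    def test_fn_zero_when_all_recovered(self):
        outs = [_outcome([1, -1, 0], [2, -2, 0])] * 4
        assert fn_rate(outs) == 0.0

    def test_rates_complement_selection_rates(self, rng):
        outs = _random_outcomes(rng)
        beta = outs[0].beta_true
        sel = np.array([o.selected for o in outs])
        tn = 1 - sel[:, beta == 0].mean(0)
        assert fp_rate(outs) == pytest.approx(1 - tn.mean())
        tp = sel[:, beta != 0].mean(0)
        assert fn_rate(outs) == pytest.approx(1 - tp.mean())

    def test_requires_relevant_coefficients(self):
        with pytest.raises(ValueError):
            fp_rate([_outcome([1, -1], [1, -1])])
        with pytest.raises(ValueError):
            fn_rate([_outcome([0, 0], [0, 0])])


class TestCoverageOfZero:
    def test_dropped_coefficient_counts_covered(self):
        outs = [_outcome([1, 0], [2.0, 0.0])]
        assert coverage_of_zero(outs, "null", "adapt") == 1.0

    def test_ci_containment_decides(self):
        ci = np.array([[np.nan, np.nan], [-0.1, 1.1]])
        outs = [_outcome([1, 0], [2.0, 0.5], ci_adapt=ci, ci_oracle=ci)]
        assert coverage_of_zero(outs, "null", "adapt") == 1.0
        ci2 = np.array([[np.nan, np.nan], [0.2, 0.8]])
        outs2 = [_outcome([1, 0], [2.0, 0.5], ci_adapt=ci2, ci_oracle=ci2)]
        assert coverage_of_zero(outs2, "null", "adapt") == 0.0

    def test_signal_set_uses_nonzero_truth(self):
        ci = np.array([[-0.5, 0.5], [np.nan, np.nan]])
        outs = [_outcome([1, 0], [1.0, 0.0], ci_adapt=ci, ci_oracle=ci)]
        assert coverage_of_zero(outs, "signal", "adapt") == 1.0

    def test_dominates_drop_fraction_per_coefficient(self, rng):
        # covered-if-dropped implies coverage >= drop fraction, coefficientwise
        outs = [o for o in _random_outcomes(rng)
                if not o.degenerate_adapt]
        beta = outs[0].beta_true
        sel = np.array([o.selected for o in outs])
        for which, mask in (("null", beta == 0), ("signal", beta != 0)):
            cov = coverage_of_zero(outs, which, "adapt")
            drop = 1 - sel[:, mask].mean(0)
            assert cov >= drop.mean() - 1e-12


class TestCoverageOfTruth:
    def test_always_covering(self):
        ci = np.array([[0.5, 1.5], [-1.5, -0.5], [np.nan, np.nan]])
        outs = [_outcome([1, -1, 0], [1, -1, 0], ci_adapt=ci, ci_oracle=ci)] * 3
        assert coverage_of_truth(outs, "oracle") == 1.0

    def test_never_covering(self):
        ci = np.array([[2.0, 3.0], [-3.0, -2.0], [np.nan, np.nan]])
        outs = [_outcome([1, -1, 0], [1, -1, 0], ci_adapt=ci, ci_oracle=ci)]
        assert coverage_of_truth(outs, "oracle") == 0.0

    def test_never_selected_coefficient_warns_and_excluded(self):
        ci = np.array([[0.5, 1.5], [np.nan, np.nan]])
        outs = [_outcome([1, -1], [1.0, 0.0], ci_adapt=ci, ci_oracle=ci)]
        with pytest.warns(UserWarning, match="never selected"):
            cov = coverage_of_truth(outs, "oracle")
        assert cov == 1.0

    def test_unconditional_variant_counts_misses(self):
        ci = np.array([[0.5, 1.5], [np.nan, np.nan]])
        outs = [_outcome([1, -1], [1.0, 0.0], ci_adapt=ci, ci_oracle=ci)]
        assert coverage_of_truth(outs, "oracle", conditional=False) == 0.5


class TestAggregateAndAudit:
    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate([], "lasso", "linear")

    def test_single_replicate_row(self):
        row = aggregate([_outcome([1, 0], [1.0, 0.0])], "lasso", "linear")
        assert row.n_reps == row.n_analysed == 1
        assert row.fp == 0.0 and row.fn == 0.0

    def test_failed_majority_marks_cell(self):
        good = _outcome([1, 0], [1.0, 0.0])
        bad = _outcome([1, 0], [0.0, 0.0], failed=True)
        row = aggregate([good, bad, bad], "lasso", "linear")
        assert row.cell_failed and np.isnan(row.fp)
        assert row.n_failed == 2

    def test_csv_roundtrip_bit_exact(self, rng):
        outs = _random_outcomes(rng)
        row = aggregate(outs, "lasso", "linear",
                        {"corr": "identity", "n": 100, "beta": 0.5,
                         "error": "normal", "predictors": "mvnormal"})
        df = pd.DataFrame([row.to_record()], columns=list(MetricsRow.COLUMNS))
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        buf.seek(0)
        back = pd.read_csv(buf, float_precision="round_trip")
        for c in ("fp", "fn", "cov_truth_adapt", "cov_truth_oracle"):
            assert back[c][0] == df[c][0]

    def test_metrics_recomputable_from_event_log(self, rng):
        # independent recount of every metric from the long-format audit log
        outs = _random_outcomes(rng)
        log = outcomes_to_frame(outs)
        row = aggregate(outs, "m", "linear")

        def recount_fp():
            per = []
            for j, bt in enumerate(outs[0].beta_true):
                if bt != 0:
                    continue
                sub = log[log.coef == j]
                per.append(sub.selected.mean())
            return float(np.mean(per))

        assert recount_fp() == pytest.approx(row.fp, abs=1e-12)

        def recount_cov_zero(which, alg):
            lo, hi = f"lo_{alg}", f"hi_{alg}"
            sub = log[~log[f"degenerate_{alg}"]]
            per = []
            for j, bt in enumerate(outs[0].beta_true):
                keep = (bt == 0) if which == "null" else (bt != 0)
                if not keep:
                    continue
                rows = sub[sub.coef == j]
                ev = [(not r.selected) or (getattr(r, lo) <= 0 <= getattr(r, hi))
                      for r in rows.itertuples()]
                per.append(np.mean(ev))
            return float(np.mean(per))

        for which in ("null", "signal"):
            for alg in ("adapt", "oracle"):
                assert recount_cov_zero(which, alg) == pytest.approx(
                    coverage_of_zero([o for o in outs], which, alg), abs=1e-12)

        def recount_cov_truth(alg):
            lo, hi = f"lo_{alg}", f"hi_{alg}"
            sub = log[~log[f"degenerate_{alg}"]]
            per = []
            for j, bt in enumerate(outs[0].beta_true):
                if bt == 0:
                    continue
                rows = sub[(sub.coef == j) & sub.selected]
                if len(rows) == 0:
                    continue
                per.append(np.mean([(getattr(r, lo) <= bt <= getattr(r, hi))
                                    for r in rows.itertuples()]))
            return float(np.mean(per))

        assert recount_cov_truth("oracle") == pytest.approx(
            row.cov_truth_oracle, abs=1e-12)
        assert recount_cov_truth("adapt") == pytest.approx(
            row.cov_truth_adapt, abs=1e-12)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=10, deadline=None)
def test_rates_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    outs = _random_outcomes(rng, R=8)
    row = aggregate(outs, "m", "linear")
    for v in (row.fp, row.fn, row.cov_zero_null_adapt, row.cov_zero_null_oracle,
              row.cov_zero_signal_adapt, row.cov_zero_signal_oracle):
        assert 0.0 <= v <= 1.0
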