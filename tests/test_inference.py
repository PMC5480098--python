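"""Adaptive and oracle post-selection inference, both families."""

import numpy as np
import pytest
from scipy.special import expit

from postsel.estimators import PenalizedFit
from postsel.inference import (select_design, adaptive_inference_linear,
                               oracle_inference_linear,
                               adaptive_inference_logistic,
                               oracle_inference_logistic,
                               confidence_intervals, SelectedInference)


def _fake_fit(beta, family="linear", intercept=0.0):
    return PenalizedFit(method="x", family=family, intercept=intercept,
                        beta=np.asarray(beta, float))


class TestSelectDesign:
    def test_empty_support_gives_intercept_column(self, rng):
        X = rng.standard_normal((10, 4))
        XS, idx = select_design(X, _fake_fit(np.zeros(4)))
        assert XS.shape == (10, 1) and np.all(XS == 1.0)
        assert idx.size == 0

    def test_column_order_follows_indices(self, rng):
        X = rng.standard_normal((10, 5))
        fit = _fake_fit([0, 2.0, 0, 0, -1.0])
        XS, idx = select_design(X, fit)
        assert idx.tolist() == [1, 4]
        assert np.array_equal(XS[:, 1], X[:, 1])
        assert np.array_equal(XS[:, 2], X[:, 4])

    def test_full_support_roundtrip(self, rng):
        X = rng.standard_normal((8, 3))
        XS, _ = select_design(X, _fake_fit([1.0, 1.0, 1.0]))
        assert np.array_equal(XS[:, 1:], X)


class TestLinear:
    def test_intercept_only_variance(self, rng):
        y = rng.standard_normal(40) + 2.0
        XS = np.ones((40, 1))
        inf = adaptive_inference_linear(XS, y, np.array([y.mean()]))
        s2 = np.sum((y - y.mean()) ** 2) / 39
        assert inf.sigma2 == pytest.approx(s2)
        assert inf.cov[0, 0] == pytest.approx(s2 / 40)

    def test_orthonormal_diagonal_covariance(self):
        n = 12
        XS = np.column_stack([np.ones(n),
                              np.tile([1.0, -1.0], n // 2)])
        rng = np.random.default_rng(2)
        y = 1.0 + 0.5 * XS[:, 1] + 0.1 * rng.standard_normal(n)
        b = np.linalg.lstsq(XS, y, rcond=None)[0]
        inf = adaptive_inference_linear(XS, y, b)
        assert np.allclose(np.diag(np.diag(inf.cov)), inf.cov, atol=1e-12)
        assert inf.cov[1, 1] == pytest.approx(inf.sigma2 / n)

    def test_adaptive_covariance_matches_inversion_oracle(self, rng):
        XS = np.column_stack([np.ones(8), rng.standard_normal((8, 2))])
        y = rng.standard_normal(8)
        b = np.array([0.1, 0.5, -0.2])
        inf = adaptive_inference_linear(XS, y, b)
        resid = y - XS @ b
        s2 = resid @ resid / (8 - 3)
        oracle_cov = s2 * np.linalg.inv(XS.T @ XS)
        assert np.allclose(inf.cov, oracle_cov, atol=1e-10)

    def test_oracle_perfect_fit_zero_width(self, rng):
        XS = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = 2.0 + 3.0 * XS[:, 1]
        inf = oracle_inference_linear(XS, y)
        assert inf.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(inf.lower, inf.upper)

    def test_oracle_matches_pseudoinverse(self, rng):
        XS = np.column_stack([np.ones(10), rng.standard_normal((10, 3))])
        y = rng.standard_normal(10)
        inf = oracle_inference_linear(XS, y)
        assert np.allclose(inf.estimates, np.linalg.pinv(XS) @ y, atol=1e-10)

    def test_oracle_invariant_to_stage1_magnitudes(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        f1 = _fake_fit([0.9, 0, 0.1, 0])
        f2 = _fake_fit([0.001, 0, 5.0, 0])
        XS1, i1 = select_design(X, f1)
        XS2, i2 = select_design(X, f2)
        a = oracle_inference_linear(XS1, y, i1)
        b = oracle_inference_linear(XS2, y, i2)
        assert np.allclose(a.estimates, b.estimates)
        assert np.allclose(a.cov, b.cov)

    def test_adaptive_equals_oracle_at_ols_full_support(self, rng):
        # an unpenalized full-support fit: both algorithms coincide
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        XS = np.column_stack([np.ones(25), X])
        bo = np.linalg.lstsq(XS, y, rcond=None)[0]
        a = adaptive_inference_linear(XS, y, bo)
        o = oracle_inference_linear(XS, y)
        assert a.sigma2 == pytest.approx(o.sigma2)
        assert np.allclose(a.cov, o.cov)

    def test_degenerate_when_p_adapt_ge_n(self, rng):
        XS = np.column_stack([np.ones(3), rng.standard_normal((3, 3))])
        inf = oracle_inference_linear(XS, rng.standard_normal(3))
        assert inf.degenerate
        assert np.all(np.isnan(inf.lower))


class TestLogistic:
    def test_null_estimates_quarter_weights(self, rng):
        XS = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = (rng.random(20) < 0.5).astype(float)
        inf = adaptive_inference_logistic(XS, y, np.zeros(2))
        oracle_cov = 4.0 * np.linalg.inv(XS.T @ XS)
        assert np.allclose(inf.cov, oracle_cov, atol=1e-10)

    def test_matches_numeric_hessian_oracle(self, rng):
        # finite-difference Hessian of the log-likelihood at beta_hat
        XS = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        y = (rng.random(20) < 0.5).astype(float)
        b = np.array([0.2, -0.4, 0.7])
        inf = adaptive_inference_logistic(XS, y, b)

        def nll(theta):
            eta = XS @ theta
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

        h = 1e-5
        H = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
                H[i, j] = (nll(b + ei + ej) - nll(b + ei) - nll(b + ej)
                           + nll(b)) / h ** 2
        assert np.allclose(inf.cov, np.linalg.inv(H), rtol=1e-3, atol=1e-5)

    def test_woolf_variance_single_binary_predictor(self):
        # 2x2 table (a, b, c, d): slope variance at the MLE is
        # 1/a + 1/b + 1/c + 1/d
        a, b, c, d = 30, 20, 15, 35     # exposed/unexposed x case/control
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        XS = np.column_stack([np.ones_like(x), x])
        inf = oracle_inference_logistic(XS, y)
        woolf = 1 / a + 1 / b + 1 / c + 1 / d
        assert inf.cov[1, 1] == pytest.approx(woolf, rel=1e-6)
        assert inf.estimates[1] == pytest.approx(np.log(a * d / (b * c)),
                                                 rel=1e-6)

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        inf = oracle_inference_logistic(np.ones((100, 1)), y)
        assert inf.estimates[0] == pytest.approx(np.log(0.3 / 0.7), rel=1e-6)

    def test_oracle_matches_irls_oracle(self, rng):
        XS = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        eta = 0.5 * XS[:, 1]
        y = (rng.random(30) < expit(eta)).astype(float)
        inf = oracle_inference_logistic(XS, y)
        # independent IRLS implementation
        th = np.zeros(3)
        for _ in range(60):
            mu = expit(XS @ th)
            W = mu * (1 - mu)
            th = th + np.linalg.solve(XS.T @ (XS * W[:, None]),
                                      XS.T @ (y - mu))
        assert np.max(np.abs(inf.estimates - th)) < 1e-6

    def test_separation_flagged_degenerate(self):
        x = np.r_[np.linspace(-2, -1, 10), np.linspace(1, 2, 10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        XS = np.column_stack([np.ones(20), x])
        inf = oracle_inference_logistic(XS, y)
        assert inf.degenerate


class TestConfidenceIntervals:
    def _inf(self, est, cov):
        return SelectedInference("oracle", "linear", np.arange(len(est) - 1),
                                 np.asarray(est, float),
                                 np.asarray(cov, float))

    def test_zero_variance_degenerate_point(self):
        inf = self._inf([1.5], [[0.0]])
        lo, hi = confidence_intervals(inf)
        assert lo[0] == hi[0] == pytest.approx(1.5)

    def test_standard_normal_quantile(self):
        inf = self._inf([0.0], [[1.0]])
        lo, hi = confidence_intervals(inf, 0.95)
        assert lo[0] == pytest.approx(-1.960, abs=5e-4)
        assert hi[0] == pytest.approx(1.960, abs=5e-4)

    def test_levels_nested(self):
        inf = self._inf([0.3, -0.2], np.diag([1.0, 2.0]))
        lo50, hi50 = map(np.copy, confidence_intervals(inf, 0.5))
        lo95, hi95 = confidence_intervals(inf, 0.95)
        assert np.all(lo95 < lo50) and np.all(hi50 < hi95)

    def test_bounds_bracket_estimate(self, rng):
        est = rng.standard_normal(3)
        A = rng.standard_normal((3, 3))
        inf = self._inf(est, A @ A.T + 0.1 * np.eye(3))
        lo, hi = confidence_intervals(inf)
        assert np.all(lo <= est) and np.all(est <= hi)


def test_covariances_symmetric_psd(rng):
    for _ in range(5):
        XS = np.column_stack([np.ones(40), rng.standard_normal((40, 3))])
        y = (rng.random(40) < 0.5).astype(float)
        inf = oracle_inference_logistic(XS, y)
        if inf.degenerate:
            continue
        assert np.allclose(inf.cov, inf.cov.T)
        assert np.linalg.eigvalsh(inf.cov)[0] >= -1e-12
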