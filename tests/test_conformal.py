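"""Conformal regression: quantile rule, interval algebra, coverage."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcmlab import conformal


def brute_force_alpha_star(alphas, epsilon):
    """Oracle from the conformal p-value definition, in exact rational
    arithmetic: a candidate score a is inside the prediction region iff
    (#{alpha_i >= a} + 1) / (n + 1) > epsilon; alpha* is the supremum of
    included scores."""
    from fractions import Fraction

    eps = Fraction(epsilon).limit_denominator(1000)
    n = len(alphas)
    if Fraction(1, n + 1) > eps:  # scores above all calibration scores pass
        return float("inf")
    included = [q for q in alphas
                if Fraction(sum(a >= q for a in alphas) + 1, n + 1) > eps]
    return max(included)


class TestNonconformity:
    def test_zero_residual(self):
        assert conformal.nonconformity(1.0, 1.0, 0.5) == 0.0

    def test_unit_score(self):
        assert conformal.nonconformity(2.0, 1.0, 0.99, beta=0.01) == pytest.approx(1.0)

    @given(st.floats(min_value=0.01, max_value=5.0))
    def test_homogeneity_in_lambda(self, spread):
        a1 = conformal.nonconformity(3.0, 1.0, spread, beta=0.5)
        a2 = conformal.nonconformity(3.0, 1.0, 2 * spread + 0.5, beta=0.5)
        assert a2 == pytest.approx(a1 * (spread + 0.5) / (2 * spread + 1.0))

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError):
            conformal.nonconformity(1.0, 0.0, 1.0, beta=0.0)

    def test_exponential_scaler(self):
        a = conformal.nonconformity(2.0, 0.0, 1.0, scaler="exponential")
        assert a == pytest.approx(2.0 / np.e)


class TestCalibrate:
    def test_hand_example_nineteen_scores(self):
        alphas = np.arange(1.0, 20.0)  # 1..19, n=19
        # k = ceil(0.95 * 20) = 19 -> the largest score
        assert conformal.calibrate(alphas, 0.05) == 19.0

    def test_tiny_calibration_set_unbounded(self):
        assert conformal.calibrate([0.3], 0.05) == float("inf")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for n in range(1, 51):
            alphas = np.sort(rng.exponential(size=n))
            for i in range(1, 51):
                eps = i / 100
                assert conformal.calibrate(alphas, eps) == brute_force_alpha_star(
                    alphas.tolist(), eps
                ), (n, eps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conformal.calibrate([], 0.05)


class TestIntervals:
    def cal(self, n=99, seed=0, beta=0.01):
        rng = np.random.default_rng(seed)
        return conformal.ConformalCalibrator(alphas=rng.exponential(size=n), beta=beta)

    def test_half_width_closed_form(self):
        calib = conformal.ConformalCalibrator(alphas=[2.0] * 99, beta=0.5)
        iv = conformal.predict_interval(np.array([1.0]), np.array([0.0]), calib, 0.05)
        # alpha* = 2, lambda = 0 + 0.5 -> half-width 1.0
        assert iv.lower[0] == pytest.approx(0.0)
        assert iv.upper[0] == pytest.approx(2.0)

    def test_wider_spread_wider_interval(self):
        calib = self.cal()
        a = conformal.predict_interval(np.zeros(1), np.array([0.1]), calib, 0.1)
        b = conformal.predict_interval(np.zeros(1), np.array([0.5]), calib, 0.1)
        assert b.width[0] > a.width[0]

    def test_nested_in_confidence(self):
        calib = self.cal()
        y_hat, spread = np.zeros(5), np.linspace(0, 1, 5)
        hi = conformal.predict_interval(y_hat, spread, calib, 0.05)
        lo = conformal.predict_interval(y_hat, spread, calib, 0.5)
        assert np.all(lo.lower >= hi.lower) and np.all(lo.upper <= hi.upper)


class TestValidityEfficiency:
    def test_validity_fractions(self):
        iv = conformal.PredictionIntervals(
            lower=np.array([0.0, 0.0]), upper=np.array([1.0, 1.0]), confidence=0.9
        )
        assert conformal.validity(iv, np.array([0.5, 0.5])) == 1.0
        assert conformal.validity(iv, np.array([0.5, 2.0])) == 0.5

    def test_length_mismatch(self):
        iv = conformal.PredictionIntervals(np.zeros(2), np.ones(2), 0.9)
        with pytest.raises(ValueError):
            conformal.validity(iv, np.zeros(3))

    def test_efficiency_summary(self):
        iv = conformal.PredictionIntervals(np.zeros(3), np.array([1.0, 2.0, 3.0]), 0.9)
        eff = conformal.efficiency(iv)
        assert eff["median"] == 2.0 and eff["n_unbounded"] == 0

    def test_unbounded_excluded_and_counted(self):
        iv = conformal.PredictionIntervals(
            np.array([0.0, 0.0]), np.array([2.0, np.inf]), 0.99
        )
        eff = conformal.efficiency(iv)
        assert eff["n_unbounded"] == 1 and eff["median"] == 2.0

    def test_constant_spread_constant_width(self):
        calib = conformal.ConformalCalibrator(alphas=np.linspace(0.1, 2, 99), beta=0.3)
        iv = conformal.predict_interval(np.zeros(4), np.zeros(4), calib, 0.1)
        assert np.allclose(iv.width, iv.width[0])


class TestCalibrationCurve:
    def exchangeable(self, n_cal=200, n_test=500, seed=0):
        rng = np.random.default_rng(seed)
        spread = rng.uniform(0.2, 1.0, size=n_cal + n_test)
        resid = rng.normal(scale=spread)
        y_hat = np.zeros(n_cal + n_test)
        y = y_hat + resid
        calib = conformal.fit_calibrator(y[:n_cal], y_hat[:n_cal], spread[:n_cal])
        return calib, y_hat[n_cal:], spread[n_cal:], y[n_cal:]

    def test_observed_error_nondecreasing_in_epsilon(self):
        calib, y_hat, spread, y = self.exchangeable()
        curve = conformal.calibration_curve(calib, y_hat, spread, y,
                                            np.arange(0.02, 0.5, 0.02))
        assert (np.diff(curve["observed_error"]) >= -1e-12).all()

    def test_tiny_epsilon_unbounded_intervals_zero_error(self):
        calib, y_hat, spread, y = self.exchangeable(n_cal=10)
        curve = conformal.calibration_curve(calib, y_hat, spread, y, [0.01])
        assert curve["observed_error"].iloc[0] == 0.0

    def test_close_to_diagonal_on_reference_run(self):
        # n_cal=1000, n_test=2000, 5 seeds: max |observed - epsilon| <= 0.05
        grid = np.arange(0.05, 0.5, 0.05)
        devs = []
        for seed in range(5):
            calib, y_hat, spread, y = self.exchangeable(n_cal=1000, n_test=2000,
                                                        seed=seed)
            curve = conformal.calibration_curve(calib, y_hat, spread, y, grid)
            devs.append(np.max(np.abs(curve["observed_error"].to_numpy() - grid)))
        assert max(devs) <= 0.05


class TestMarginalCoverage:
    @pytest.mark.parametrize("epsilon", [0.05, 0.10, 0.20, 0.32])
    def test_mean_coverage_across_runs(self, epsilon):
        # exchangeable runs; mean coverage over 25 seeds >= 1-eps - 3*SE
        n_cal, n_test, n_runs = 150, 300, 25
        covers = []
        for seed in range(n_runs):
            rng = np.random.default_rng([seed, 7])
            spread = rng.uniform(0.1, 1.0, size=n_cal + n_test)
            y = rng.normal(scale=spread)
            calib = conformal.fit_calibrator(y[:n_cal], np.zeros(n_cal), spread[:n_cal])
            iv = conformal.predict_interval(np.zeros(n_test), spread[n_cal:], calib,
                                            epsilon)
            covers.append(conformal.validity(iv, y[n_cal:]))
        mean_cov = np.mean(covers)
        # per-run coverage varies both through the binomial over test points
        # and through the random calibration quantile; use the empirical
        # across-run SE of the mean
        se = np.std(covers, ddof=1) / np.sqrt(n_runs)
        assert mean_cov >= 1 - epsilon - 3 * se

    def test_normalized_intervals_tighter_than_constant_lambda(self):
        # with an informative spread, per-instance normalization gives
        # narrower intervals than a constant scaler at matched coverage
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng([seed, 11])
            n_cal, n_test = 500, 1000
            spread = rng.uniform(0.05, 2.0, size=n_cal + n_test)
            y = rng.normal(scale=spread)
            calib_norm = conformal.fit_calibrator(y[:n_cal], np.zeros(n_cal),
                                                  spread[:n_cal])
            calib_const = conformal.fit_calibrator(y[:n_cal], np.zeros(n_cal),
                                                   np.zeros(n_cal), beta=1.0)
            iv_n = conformal.predict_interval(np.zeros(n_test), spread[n_cal:],
                                              calib_norm, 0.1)
            iv_c = conformal.predict_interval(np.zeros(n_test), np.zeros(n_test),
                                              calib_const, 0.1)
            cov_n = conformal.validity(iv_n, y[n_cal:])
            cov_c = conformal.validity(iv_c, y[n_cal:])
            assert abs(cov_n - cov_c) < 0.05  # both calibrated
            ratios.append(iv_n.width.mean() / iv_c.width.mean())
        assert np.mean(ratios) < 1.0
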