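import dataclasses

import numpy as np
import pytest
from scipy import signal, stats

import rhythmfit as rf
from rhythmfit import (
    RhythmTestConfig,
    TimeCourse,
    differential_rhythmicity_test,
    harmonic_regression_fit,
    jtk_cycle_test,
    linear_detrend,
    lomb_scargle_periodogram,
    ls_permutation_test,
    umbrella_rain_test,
)
from rhythmfit.rhythm import kendall_tau
from conftest import make_tc


def _constant_tc():
    return TimeCourse(("c", "g"), np.arange(0, 49, 4.0), np.full((13, 3), 2.0))


class TestLinearDetrend:
    def test_pure_line_residuals_zero(self):
        t = np.arange(0, 49, 4.0)
        vals = np.tile((0.7 * t + 2.0)[:, None], (1, 4))
        tc = TimeCourse(("c", "g"), t, vals)
        out = linear_detrend(tc)
        assert np.abs(out.values).max() <= 1e-10
        assert out.meta["detrend"]["slope"] == pytest.approx(0.7)
        assert out.meta["detrend"]["intercept"] == pytest.approx(2.0)

    def test_cosine_plus_line_residual_slope_zero(self, cos24):
        p = dataclasses.replace(cos24, slope=0.05)
        tc = make_tc(p, noise_sd=0.0)
        out = linear_detrend(tc)
        t, y = out.observations()
        refit_slope = np.polyfit(t, y, 1)[0]
        assert refit_slope == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self, cos24):
        tc = make_tc(cos24, noise_sd=0.2, seed=1)
        once = linear_detrend(tc)
        twice = linear_detrend(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_needs_three_time_points(self):
        tc = TimeCourse(("c", "g"), [0.0, 4.0], [[1.0], [2.0]])
        with pytest.raises(ValueError, match=">= 3"):
            linear_detrend(tc)


class TestPeriodogram:
    def test_peak_at_true_period(self, cos24):
        tc = make_tc(cos24, noise_sd=0.0)
        periods, power = lomb_scargle_periodogram(tc)
        best = periods[np.argmax(power)]
        grid_step = np.abs(np.diff(np.sort(periods)))
        step_at_24 = grid_step[np.argmin(np.abs(np.sort(periods)[:-1] - 24.0))]
        assert abs(best - 24.0) <= step_at_24 + 1e-9

    def test_constant_series_all_zero(self):
        periods, power = lomb_scargle_periodogram(_constant_tc())
        np.testing.assert_array_equal(power, 0.0)

    def test_true_period_beats_half_period(self, cos24):
        tc = make_tc(cos24, noise_sd=0.0)
        periods, power = lomb_scargle_periodogram(tc)
        p_true = power[np.argmin(np.abs(periods - 24.0))]
        p_half = power[np.argmin(np.abs(periods - 12.0))]
        assert p_true > p_half

    def test_matches_scipy_reference(self, cos24):
        # dual route: our vectorized periodogram vs scipy.signal.lombscargle
        tc = make_tc(cos24, noise_sd=0.3, seed=5)
        cfg = RhythmTestConfig()
        periods, power = lomb_scargle_periodogram(tc, cfg)
        t, y = tc.observations()
        yc = y - y.mean()
        ref = signal.lombscargle(t, yc, 2 * np.pi / periods)
        np.testing.assert_allclose(
            power, ref / np.var(y, ddof=1), rtol=1e-8, atol=1e-10
        )

    def test_too_few_points(self):
        tc = TimeCourse(("c", "g"), [0.0, 4.0, 8.0], [[1.0], [2.0], [0.5]])
        with pytest.raises(ValueError, match=">= 4"):
            lomb_scargle_periodogram(tc)


class TestLsPermutation:
    def test_floor_when_observed_beats_all(self, cos24):
        tc = make_tc(cos24, noise_sd=0.0)
        cfg = RhythmTestConfig(n_permutations=5000, seed=0)
        res = ls_permutation_test(tc, cfg)
        assert res.p_value == pytest.approx(1.0 / 5001.0)
        assert res.period_estimate == pytest.approx(24.0, abs=4.0)

    def test_constant_series(self):
        res = ls_permutation_test(_constant_tc(), RhythmTestConfig(n_permutations=50))
        assert res.p_value == 1.0
        assert res.flags.get("constant_series")

    def test_seeded_determinism(self, cos24):
        tc = make_tc(cos24, noise_sd=0.8, seed=2)
        cfg = RhythmTestConfig(n_permutations=200, seed=5)
        assert ls_permutation_test(tc, cfg).p_value == ls_permutation_test(tc, cfg).p_value


def _oracle_tau(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    n = len(x)
    num = 0
    tx = ty = 0
    n0 = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(x[i] - x[j])
            b = np.sign(y[i] - y[j])
            num += a * b
            tx += a == 0
            ty += b == 0
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return num / denom if denom else np.nan


class TestKendallTau:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.choice([0.0, 1.0, 2.0], size=8)  # force ties
        assert kendall_tau(x, y) == pytest.approx(_oracle_tau(x, y), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert kendall_tau(x, y) == pytest.approx(
            stats.kendalltau(x, y).statistic, abs=1e-12
        )

    def test_perfect_concordance(self):
        x = np.arange(10.0)
        assert kendall_tau(x, 2 * x + 1) == 1.0


class TestJtk:
    def test_template_data_gives_tau_one(self):
        t = np.arange(0, 49, 4.0)
        vals = np.cos(2 * np.pi * (t - 8.0) / 24.0)[:, None]
        tc = TimeCourse(("c", "g"), t, vals)
        res = jtk_cycle_test(tc, RhythmTestConfig(n_permutations=100, seed=0))
        assert res.statistic == pytest.approx(1.0)
        assert res.period_estimate == 24.0
        assert res.phase_estimate == 8.0

    def test_negated_template_matches_antiphase(self):
        # -cos(.-8) == cos(.-20); duplicate data values at t and t+24 are
        # exact ties while the recomputed template differs by ~1 ulp, so tau
        # stays marginally below 1 - assert template selection instead
        t = np.arange(0, 49, 4.0)
        vals = -np.cos(2 * np.pi * (t - 8.0) / 24.0)
        tc = TimeCourse(("c", "g"), t, vals[:, None])
        res = jtk_cycle_test(tc, RhythmTestConfig(n_permutations=100, seed=0))
        assert res.period_estimate == 24.0
        assert res.phase_estimate == pytest.approx((8.0 + 12.0) % 24.0)
        antiphase = np.cos(2 * np.pi * (t - 20.0) / 24.0)
        assert res.statistic == pytest.approx(kendall_tau(vals, antiphase), abs=1e-9)
        assert res.statistic > 0.9

    def test_constant_series_p_one(self):
        res = jtk_cycle_test(_constant_tc(), RhythmTestConfig(n_permutations=50))
        assert res.p_value == 1.0
        assert res.flags.get("constant_series")

    def test_monotone_transform_invariance(self, cos24):
        tc = make_tc(cos24, noise_sd=0.3, seed=3)
        cfg = RhythmTestConfig(n_permutations=100, seed=9)
        a = jtk_cycle_test(tc, cfg)
        b = jtk_cycle_test(tc.with_values(np.exp(tc.values)), cfg)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == b.p_value


class TestUmbrellaRain:
    def test_sawtooth_peak_recovered(self):
        t = np.arange(0, 49, 4.0)
        folded = t % 24.0
        vals = np.where(folded <= 12.0, folded, 24.0 - folded).astype(float)
        rng = np.random.default_rng(0)
        vals = vals[:, None] + rng.normal(0, 1e-6, (13, 3))  # break ties only
        tc = TimeCourse(("c", "g"), t, vals)
        res = umbrella_rain_test(tc, RhythmTestConfig(n_permutations=2000, seed=1))
        assert res.p_value == pytest.approx(1.0 / 2001.0)
        assert res.phase_estimate == pytest.approx(12.0)

    def test_constant_series_p_one(self):
        res = umbrella_rain_test(_constant_tc(), RhythmTestConfig(n_permutations=50))
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self, cos24):
        tc = make_tc(cos24, noise_sd=0.3, seed=4)
        cfg = RhythmTestConfig(n_permutations=100, seed=7)
        a = umbrella_rain_test(tc, cfg)
        b = umbrella_rain_test(tc.with_values(np.exp(tc.values)), cfg)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.p_value == b.p_value

    def test_needs_five_positions(self):
        tc = TimeCourse(("c", "g"), np.arange(0, 48, 12.0), np.ones((4, 2)))
        with pytest.raises(ValueError, match=">= 5"):
            umbrella_rain_test(tc, RhythmTestConfig(n_permutations=10))


class TestHarmonicRegression:
    def test_recovers_amplitude_and_phase(self, cos24):
        tc = make_tc(cos24, noise_sd=0.0)
        fit = harmonic_regression_fit(tc, period=24.0)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-9)
        assert fit.peak_time == pytest.approx(6.0, abs=1e-9)
        assert fit.mesor == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_zero_coefficients(self):
        fit = harmonic_regression_fit(_constant_tc(), period=24.0)
        assert fit.mesor == pytest.approx(2.0)
        assert fit.cos_coef == pytest.approx(0.0, abs=1e-12)
        assert fit.sin_coef == pytest.approx(0.0, abs=1e-12)

    def test_noise_coefficients_near_zero(self, white_noise_factory):
        amps = [
            harmonic_regression_fit(white_noise_factory(seed), period=24.0).amplitude
            for seed in range(40)
        ]
        # E[amplitude]^2 ~ 2 * sigma^2 * 2/n; sigma=1, n=78 -> amp ~ 0.2
        assert np.mean(amps) < 0.5

    def test_robust_matches_ols_on_clean_data(self, cos24):
        tc = make_tc(cos24, noise_sd=0.0)
        ols = harmonic_regression_fit(tc, period=24.0, robust=False)
        rob = harmonic_regression_fit(tc, period=24.0, robust=True)
        assert rob.cos_coef == pytest.approx(ols.cos_coef, abs=1e-6)
        assert rob.sin_coef == pytest.approx(ols.sin_coef, abs=1e-6)

    def test_collinear_period_rejected(self):
        # period equal to the sampling interval aliases onto the intercept
        tc = _constant_tc()
        vals = tc.values + np.random.default_rng(0).normal(0, 1, tc.values.shape)
        tc = tc.with_values(vals)
        with pytest.raises(ValueError, match="collinear"):
            harmonic_regression_fit(tc, period=4.0)


class TestDifferentialRhythmicity:
    def test_identical_series(self, cos24):
        tc = make_tc(cos24, noise_sd=0.1, seed=6)
        res = differential_rhythmicity_test(tc, tc)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_antiphase_pair_rejected(self, cos24):
        shifted = dataclasses.replace(cos24, phase=cos24.phase + 12.0)
        a = make_tc(cos24, noise_sd=0.01, seed=7)
        b = make_tc(shifted, noise_sd=0.01, seed=8)
        res = differential_rhythmicity_test(a, b, period=24.0)
        assert res.p_value < 1e-10

    def test_detrending_is_applied(self, cos24):
        trended = dataclasses.replace(cos24, slope=0.1)
        a = make_tc(cos24, noise_sd=0.01, seed=9)
        b = make_tc(trended, noise_sd=0.01, seed=10)
        # same rhythm, different trend: detrending should keep p large
        res = differential_rhythmicity_test(a, b, period=24.0)
        assert res.p_value > 0.01
        assert res.detrend_b["slope"] == pytest.approx(0.1, abs=0.02)

    def test_mismatched_grids_error(self, cos24):
        a = make_tc(cos24)
        b = make_tc(cos24, dt=8.0)
        with pytest.raises(ValueError, match="time grids differ"):
            differential_rhythmicity_test(a, b)

    def test_permutation_option(self, cos24):
        shifted = dataclasses.replace(cos24, phase=cos24.phase + 12.0)
        a = make_tc(cos24, noise_sd=0.05, seed=11)
        b = make_tc(shifted, noise_sd=0.05, seed=12)
        res = differential_rhythmicity_test(
            a, b, period=24.0, n_permutations=500, seed=1
        )
        assert res.method == "label_permutation"
        assert res.p_value == pytest.approx(1.0 / 501.0)


class TestDifferentialCalibration:
    def test_null_pair_permutation_p_uniform(self, flat):
        from scipy.stats import kstest

        pvals = []
        for i in range(1200):
            a = rf.generate_null(
                rf.GeneratorConfig(params=flat, noise_sd=1.0, seed=10_000 + i)
            )
            b = rf.generate_null(
                rf.GeneratorConfig(params=flat, noise_sd=1.0, seed=20_000 + i)
            )
            pvals.append(
                differential_rhythmicity_test(
                    a, b, robust=False, n_permutations=199, seed=i
                ).p_value
            )
        assert kstest(pvals, "uniform").statistic < 0.05


class TestPermutationFloorProperty:
    @pytest.mark.parametrize("n_perm", [19, 99])
    def test_floor_respected(self, cos24, n_perm):
        tc = make_tc(cos24, noise_sd=0.0)
        cfg = RhythmTestConfig(n_permutations=n_perm, seed=0)
        for fn in (ls_permutation_test, jtk_cycle_test, umbrella_rain_test):
            p = fn(tc, cfg).p_value
            assert p >= 1.0 / (n_perm + 1) - 1e-12
            assert p <= 1.0
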