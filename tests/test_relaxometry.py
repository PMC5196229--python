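"""Relaxation fitting, group statistics, tumour volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aquadiff as aq
from aquadiff.errors import ConfigurationError, FittingError
from aquadiff.relaxometry import (
    DEFAULT_TR_GRID_MS,
    RelaxationSeries,
    SeriesKind,
)
from aquadiff.synthetic import NoiseModel, gen_relaxation_series


class TestFitT1:
    def test_exact_on_noiseless_protocol_grid(self):
        series = gen_relaxation_series(SeriesKind.T1_RECOVERY, 1500.0, 100.0)
        t1, s0 = aq.fit_t1(series)
        assert t1 == pytest.approx(1500.0, rel=1e-6)
        assert s0 == pytest.approx(100.0, rel=1e-6)

    @given(t1=st.floats(100.0, 4000.0), s0=st.floats(1.0, 1e4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_over_random_parameters(self, t1, s0):
        series = gen_relaxation_series(SeriesKind.T1_RECOVERY, t1, s0)
        t1_hat, s0_hat = aq.fit_t1(series)
        assert t1_hat == pytest.approx(t1, rel=1e-5)
        assert s0_hat == pytest.approx(s0, rel=1e-5)

    def test_small_noise_bias_below_two_percent(self):
        t1_true, s0 = 1500.0, 100.0
        fits = []
        for rep in range(500):
            series = gen_relaxation_series(
                SeriesKind.T1_RECOVERY, t1_true, s0,
                noise=NoiseModel(sigma=0.01 * s0, seed=rep),
            )
            fits.append(aq.fit_t1(series)[0])
        assert abs(np.mean(fits) - t1_true) / t1_true < 0.02

    def test_constant_signal_unidentifiable(self):
        series = RelaxationSeries(
            SeriesKind.T1_RECOVERY, np.array(DEFAULT_TR_GRID_MS), np.full(10, 55.0)
        )
        with pytest.raises(FittingError):
            aq.fit_t1(series)


class TestFitT2:
    def test_exact_on_noiseless_echo_train(self):
        series = gen_relaxation_series(SeriesKind.T2_ECHO_TRAIN, 80.0, 100.0)
        t2, s0 = aq.fit_t2(series, n_echoes_used=19)
        assert t2 == pytest.approx(80.0, rel=1e-9)
        assert s0 == pytest.approx(100.0, rel=1e-9)

    def test_two_echo_exact_solution(self):
        series = gen_relaxation_series(SeriesKind.T2_ECHO_TRAIN, 60.0, 50.0)
        t2, s0 = aq.fit_t2(series, n_echoes_used=2)
        assert t2 == pytest.approx(60.0, rel=1e-9)

    def test_truncation_direction_on_biexponential_decay(self):
        # late echoes are dominated by the slow component: the full-train
        # fit (brute-force oracle) must report a longer apparent T2 than
        # the 19-echo window that excludes it
        t = 11.0 * np.arange(1, 64)
        S = 70.0 * np.exp(-t / 40.0) + 30.0 * np.exp(-t / 200.0)
        series = RelaxationSeries(SeriesKind.T2_ECHO_TRAIN, t, S)
        t2_window, _ = aq.fit_t2(series, n_echoes_used=19)
        t2_full, _ = aq.fit_t2(series, n_echoes_used=63)
        assert t2_full > t2_window

    def test_nonlinear_matches_loglinear_on_exact_data(self):
        series = gen_relaxation_series(SeriesKind.T2_ECHO_TRAIN, 95.0, 80.0)
        lin = aq.fit_t2(series)
        nl = aq.fit_t2(series, nonlinear=True)
        assert nl[0] == pytest.approx(lin[0], rel=1e-6)

    def test_nonpositive_signal_in_window_rejected(self):
        t = 11.0 * np.arange(1, 20)
        S = 100.0 * np.exp(-t / 30.0)
        S[5] = -1.0
        with pytest.raises(FittingError):
            aq.fit_t2(RelaxationSeries(SeriesKind.T2_ECHO_TRAIN, t, S))


class TestCompareGroups:
    def test_identical_groups(self):
        cmp = aq.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.percent_change == 0.0
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_closed_form(self):
        a = np.array([200.0, 210.0, 190.0])
        b = np.array([100.0, 95.0, 105.0])
        cmp = aq.compare_groups(a, b)
        assert cmp.percent_change == pytest.approx(100.0)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(a) + len(b) - 2)
        assert cmp.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert cmp.p_value == pytest.approx(p_hand, rel=1e-12)
        assert cmp.test_variant == "homoscedastic"

    def test_paired_variant(self):
        a = [110.0, 108.0, 115.0, 120.0]
        b = [100.0, 101.0, 104.0, 109.0]
        cmp = aq.compare_groups(a, b, paired=True)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert cmp.t_statistic == pytest.approx(float(t_ref))
        assert cmp.p_value == pytest.approx(float(p_ref))
        assert cmp.test_variant == "paired"

    def test_welch_coincides_with_pooled_for_equal_variance_balanced(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 6)
        b = rng.normal(11, 1, 6)
        cmp = aq.compare_groups(a, b)
        # equal n: Welch and pooled t statistics are identical
        assert cmp.welch_t == pytest.approx(cmp.t_statistic, rel=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        n_sims, n = 4000, 4
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(100, 10, n)
            b = rng.normal(100, 10, n)
            if aq.compare_groups(a, b).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3 * se

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(7)
        powers = []
        for shift in (0.0, 10.0, 30.0):
            hits = 0
            for _ in range(400):
                a = rng.normal(100 + shift, 10, 4)
                b = rng.normal(100, 10, 4)
                if aq.compare_groups(a, b).p_value < 0.05:
                    hits += 1
            powers.append(hits / 400)
        assert powers[0] < powers[1] < powers[2]

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            aq.compare_groups([1.0, 2.0], [-1.0, 1.0])

    def test_minimum_replicates(self):
        with pytest.raises(ConfigurationError):
            aq.compare_groups([1.0], [1.0, 2.0])


class TestTumorVolume:
    @pytest.mark.parametrize(
        "short,long,expected", [(0.0, 5.0, 0.0), (2.0, 3.0, 6.24), (3.0, 2.0, 9.36)]
    )
    def test_hand_values_and_asymmetry(self, short, long, expected):
        assert aq.tumor_volume(short, long) == pytest.approx(expected)

    def test_negative_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            aq.tumor_volume(-1.0, 2.0)
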