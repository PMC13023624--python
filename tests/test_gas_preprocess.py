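"""Gas-log preprocessing: STP normalization, blank subtraction, production
series, timing statistics and termination detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomethane import gas_preprocess as gp
from conftest import preprocess_sim


def make_log(hours, increments, temp=273.15, pres=101.325, ch4=1.0, channel="ch"):
    return pd.DataFrame(
        {
            "channel_id": channel,
            "time_h": hours,
            "volume_increment_ml": increments,
            "temperature_k": temp,
            "pressure_kpa": pres,
            "ch4_fraction": ch4,
        }
    )


class TestNormalizeToSTP:
    @pytest.mark.parametrize(
        "volume,temp,pres,expected",
        [
            (100.0, 273.15, 101.325, 100.0),  # identity at STP
            (100.0, 308.15, 101.325, 100.0 * 273.15 / 308.15),  # mesophilic meter
            (100.0, 273.15, 202.65, 200.0),  # pressure doubling
        ],
    )
    def test_ideal_gas_ratio(self, volume, temp, pres, expected):
        assert gp.normalize_to_stp(volume, temp, pres) == pytest.approx(expected, rel=1e-12)

    def test_mesophilic_value_to_printed_precision(self):
        assert gp.normalize_to_stp(100.0, 308.15, 101.325) == pytest.approx(88.64, abs=5e-3)

    @pytest.mark.parametrize("temp,pres", [(0.0, 101.325), (-1.0, 101.325), (298.0, 0.0)])
    def test_nonpositive_conditions_rejected(self, temp, pres):
        with pytest.raises(ValueError):
            gp.normalize_to_stp(10.0, temp, pres)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            gp.normalize_to_stp(-1.0, 298.0, 101.325)

    @settings(deadline=None, derandomize=True)
    @given(
        v=st.floats(0, 1e4),
        t=st.floats(250, 350),
        p=st.floats(80, 120),
        scale=st.floats(0.1, 10),
    )
    def test_multiplicative_in_volume(self, v, t, p, scale):
        a = gp.normalize_to_stp(v * scale, t, p)
        b = gp.normalize_to_stp(v, t, p) * scale
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)


class TestSpecificMethaneCurve:
    def setup_method(self):
        hours = np.arange(1.0, 25.0)
        blank_inc = np.full(hours.size, 0.5)  # per 1 g inoculum VS
        self.hours = hours
        self.blank_abs = np.cumsum(blank_inc)
        self.blank_curve = gp.YieldCurve(
            np.concatenate([[0.0], hours / 24.0]),
            np.concatenate([[0.0], self.blank_abs]),
        )

    def test_double_blank_recovers_blank_absolute(self):
        """Test at 2x the scaled blank with 1 g substrate VS equals the
        blank's absolute cumulative values."""
        meta = gp.ChannelMeta("t1", "G", substrate_vs=1.0, inoculum_vs=1.0)
        log = make_log(self.hours, np.full(self.hours.size, 1.0))
        curve = gp.specific_methane_curve(log, meta, self.blank_curve)
        np.testing.assert_allclose(curve.cumulative[1:], self.blank_abs, rtol=1e-12)

    def test_test_equal_to_blank_gives_zero_curve(self):
        meta = gp.ChannelMeta("t1", "G", substrate_vs=5.0, inoculum_vs=1.0)
        log = make_log(self.hours, np.full(self.hours.size, 0.5))
        curve = gp.specific_methane_curve(log, meta, self.blank_curve)
        assert np.all(curve.cumulative == 0.0)

    def test_blank_exceeding_test_flags_curve(self):
        meta = gp.ChannelMeta("t1", "G", substrate_vs=1.0, inoculum_vs=2.0)
        log = make_log(self.hours, np.full(self.hours.size, 0.5))
        with pytest.warns(UserWarning, match="blank production exceeds"):
            curve = gp.specific_methane_curve(log, meta, self.blank_curve)
        assert curve.flagged
        assert np.all(curve.cumulative == 0.0)  # clamped, monotone

    def test_missing_ch4_fraction_on_methane_basis_errors(self):
        meta = gp.ChannelMeta("t1", "G", substrate_vs=1.0, inoculum_vs=1.0)
        log = make_log(self.hours, np.full(self.hours.size, 1.0), ch4=np.nan)
        with pytest.raises(ValueError, match="CH4 fraction"):
            gp.specific_methane_curve(log, meta, self.blank_curve)

    def test_zero_noise_round_trip_recovers_truth(self, clean_sim):
        """Preprocessing of zero-noise generated logs reproduces the
        ground-truth specific curves to <= 1e-9 relative."""
        curves, metas = preprocess_sim(clean_sim)
        for curve, meta in zip(curves, metas):
            truth = clean_sim.truth["groups"][meta.group_label]["true_curve"]
            err = np.max(np.abs(curve.cumulative - truth.at(curve.times))) / truth.final
            assert err <= 1e-9

    def test_output_always_monotone(self, noisy_sim):
        curves, _ = preprocess_sim(noisy_sim)
        for curve in curves:
            assert np.all(np.diff(curve.cumulative) >= 0)


class TestProductionSeries:
    def test_first_differences(self):
        curve = gp.YieldCurve(np.array([0.0, 1, 2, 3]), np.array([0.0, 100, 150, 160]))
        daily = gp.daily_and_hourly_production(curve)["daily"]
        np.testing.assert_allclose(daily["production"], [100, 50, 10])
        assert list(daily["day"]) == [1, 2, 3]

    def test_constant_slope_gives_equal_days(self):
        t = np.linspace(0, 10, 241)
        curve = gp.YieldCurve(t, 30.0 * t)
        daily = gp.daily_and_hourly_production(curve)["daily"]
        np.testing.assert_allclose(daily["production"], 30.0)

    def test_daily_sum_reproduces_final_exactly(self, gompertz_curve):
        # telescoping identity: differences sum to final minus initial
        curve, _ = gompertz_curve
        span = curve.final - curve.cumulative[0]
        out = gp.daily_and_hourly_production(curve)
        assert out["daily"]["production"].sum() == pytest.approx(span, rel=0, abs=1e-9)
        assert out["hourly"]["production"].sum() == pytest.approx(span, rel=0, abs=1e-9)

    def test_peak_day_matches_brute_force(self, gompertz_curve):
        curve, _ = gompertz_curve
        daily = gp.daily_and_hourly_production(curve)["daily"]
        # brute force: cumulative at integer days, argmax of differences
        cum = curve.at(np.arange(0.0, 26.0))
        brute = int(np.argmax(np.diff(cum))) + 1
        assert int(daily.loc[daily["production"].idxmax(), "day"]) == brute


class TestTimingStats:
    def test_half_reached_during_day_one(self):
        # 50% of the final value is passed during the first day
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        curve = gp.YieldCurve(t, np.array([0.0, 40.0, 60.0, 90.0, 100.0]))
        assert gp.timing_stats(curve).t50 == 1.0

    def test_linear_cumulative_over_25_days(self):
        t = np.arange(0.0, 26.0)
        curve = gp.YieldCurve(t, 4.0 * t)
        stats = gp.timing_stats(curve)
        assert stats.t50 == 13.0  # cum(12.5) = 50%, first whole day is 13
        assert stats.t90 == 23.0

    def test_fraction_one_returns_final_day(self, gompertz_curve):
        curve, _ = gompertz_curve
        stats = gp.timing_stats(curve, fractions=[1.0])
        assert stats.fraction_days[1.0] == curve.times[-1]

    def test_all_zero_curve_errors(self):
        curve = gp.YieldCurve(np.arange(0.0, 5.0), np.zeros(5))
        with pytest.raises(ValueError, match="all-zero"):
            gp.timing_stats(curve)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=3, max_size=30), st.data())
    def test_monotone_in_fraction(self, increments, data):
        cum = np.concatenate([[0.0], np.cumsum(increments)])
        if cum[-1] <= 0:
            return
        curve = gp.YieldCurve(np.arange(float(len(cum))), cum)
        stats = gp.timing_stats(curve)
        assert stats.t50 <= stats.t90 <= stats.t95


class TestDetectTermination:
    def test_hand_evaluated_series(self):
        # days 4-6 each produce < 1% of the running total
        assert gp.detect_termination([500, 300, 100, 5, 4, 3]) == 6

    def test_constant_production_never_terminates(self):
        assert gp.detect_termination([10.0] * 50) is None

    def test_trailing_zero_days_terminate_at_last_day(self):
        assert gp.detect_termination([100, 50, 20, 0, 0, 0]) == 6

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            daily = rng.exponential(50.0, n) * np.exp(-0.3 * np.arange(n))
            expected = None
            total = 0.0
            streak = 0
            for i, d in enumerate(daily):
                total += d
                streak = streak + 1 if d < 0.01 * total else 0
                if streak >= 3 and expected is None:
                    expected = i + 1
            assert gp.detect_termination(daily) == expected
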