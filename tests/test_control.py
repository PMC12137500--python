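"""Control law: discrimination, proportional formula, thresholds, loop."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoloop import (
    ControllerConfig,
    LaserCalibration,
    classify_sample,
    control_step,
    run_loop,
)
from thermoloop.errors import ConfigurationError, TimingError

from conftest import ConstantFrameSource, NullSink, uniform_frame

CFG = ControllerConfig(target_temp=42.5)


def naive_law(measured, target, g, low=-1.0, high=0.6, floor=0.0):
    """Independent, literal transcription of the published rule."""
    diff = measured - target
    if diff < low:
        return 100.0
    if diff > high:
        return floor
    return min(100.0, max(0.0, (50.0 + g) - diff * (50.0 - g)))


class TestClassifySample:
    @pytest.mark.parametrize(
        "t0, t5, expected",
        [
            (25.0, 32.0, 0.0),   # 7 degC rise: fast sample keeps g = 0
            (25.0, 28.0, 30.0),  # 3 degC rise: slow sample, g = 30
            (25.0, 30.0, 30.0),  # exactly 5 degC is not 'higher than 5'
        ],
    )
    def test_five_second_rise_rule(self, t0, t5, expected):
        assert classify_sample(t0, t5, CFG) == expected


class TestControlStep:
    @pytest.mark.parametrize(
        "measured, g, expected",
        [
            (41.0, 0.0, 100.0),   # below target - 1.0: full power
            (41.0, 30.0, 100.0),
            (42.5, 0.0, 50.0),    # zero error, fast gain
            (42.5, 30.0, 80.0),   # zero error, slow gain
            (41.5, 0.0, 100.0),   # formula continuous with full-power override
            (43.2, 0.0, 0.0),     # above target + 0.6: floor (laser off)
            (43.2, 30.0, 0.0),
        ],
    )
    def test_worked_examples(self, measured, g, expected):
        assert control_step(measured, CFG, g) == pytest.approx(expected)

    @pytest.mark.parametrize("g", [0.0, 10.0, 30.0, 50.0])
    def test_continuity_at_lower_band_edge(self, g):
        # (50 + g) + (50 - g) == 100 for every g: no jump at diff = -1
        assert control_step(CFG.target_temp + CFG.low_threshold, CFG, g) == pytest.approx(100.0)

    def test_agrees_with_naive_reference_on_grid(self):
        diffs = np.linspace(-0.999, 0.599, 401)
        for g in (0.0, 15.0, 30.0, 45.0):
            for d in diffs:
                got = control_step(42.5 + d, CFG, g)
                assert got == pytest.approx(naive_law(42.5 + d, 42.5, g), abs=1e-12)

    @given(
        m1=st.floats(30.0, 55.0),
        m2=st.floats(30.0, 55.0),
        g=st.floats(0.0, 50.0),
    )
    def test_monotone_non_increasing_in_measured(self, m1, m2, g):
        lo, hi = sorted((m1, m2))
        assert control_step(lo, CFG, g) >= control_step(hi, CFG, g)

    @given(m=st.floats(20.0, 80.0), g=st.floats(0.0, 50.0))
    def test_output_bounded(self, m, g):
        out = control_step(m, CFG, g)
        assert CFG.floor_percent <= out <= 100.0

    def test_non_finite_measurement_raises_sensor_fault(self):
        from thermoloop.errors import SensorFault

        with pytest.raises(SensorFault):
            control_step(math.nan, CFG, 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ControllerConfig(target_temp=42.5, low_threshold=1.0, high_threshold=0.5)
        with pytest.raises(ConfigurationError):
            ControllerConfig(target_temp=42.5, g_slow=60.0)


class TestCalibration:
    def test_percent_power_current_endpoints(self):
        cal = LaserCalibration(max_power=3.0, i_threshold=0.5, i_max=3.5)
        assert cal.percent_to_power(100.0) == pytest.approx(3.0)
        assert cal.percent_to_power(0.0) == 0.0
        assert cal.power_to_current(0.0) == pytest.approx(0.5)
        assert cal.power_to_current(3.0) == pytest.approx(3.5)

    def test_round_trips(self):
        cal = LaserCalibration()
        for p in np.linspace(0, 3, 13):
            assert cal.current_to_power(cal.power_to_current(p)) == pytest.approx(p, abs=1e-9)
            assert cal.percent_to_power(cal.power_to_percent(p)) == pytest.approx(p, abs=1e-9)

    def test_percent_outside_range_rejected(self):
        cal = LaserCalibration()
        for bad in (-1.0, 100.5):
            with pytest.raises(ConfigurationError):
                cal.percent_to_power(bad)


class TestRunLoop:
    def test_constant_source_at_target_settles_to_formula_value(self):
        # zero rise -> slow gain; at zero error the formula gives 50 + g = 80
        record = run_loop(CFG, ConstantFrameSource(42.5), NullSink(), 20.0)
        post = record.data[record.data["time_s"] > CFG.discrimination_window]
        np.testing.assert_allclose(post["output_percent"].to_numpy(), 80.0)
        assert np.all(post["g_coefficient"] == 30.0)

    def test_gain_changes_once_at_end_of_window(self):
        record = run_loop(CFG, ConstantFrameSource(42.5), NullSink(), 20.0)
        g = record.data["g_coefficient"].to_numpy()
        t = record.data["time_s"].to_numpy()
        changes = np.nonzero(np.diff(g))[0]
        assert len(changes) == 1
        t_switch = t[changes[0] + 1]
        assert CFG.discrimination_window <= t_switch < CFG.discrimination_window + CFG.loop_period

    def test_frozen_source_repeats_command_with_stale_flag(self):
        class FrozenSource:
            def latest_frame(self, t):
                return uniform_frame(42.5, timestamp=0.0)

        record = run_loop(CFG, FrozenSource(), NullSink(), 2.0)
        assert record.data["stale"].tolist() == [False, True, True, True, True, True]
        assert record.data["output_percent"].nunique() == 1

    def test_zero_duration_gives_empty_record(self):
        record = run_loop(CFG, ConstantFrameSource(42.5), NullSink(), 0.0)
        assert len(record) == 0

    def test_no_frame_at_start_aborts(self):
        class EmptySource:
            def latest_frame(self, t):
                return None

        with pytest.raises(TimingError):
            run_loop(CFG, EmptySource(), NullSink(), 10.0)

    def test_non_finite_reading_holds_command_and_flags_fault(self):
        class GlitchSource:
            def latest_frame(self, t):
                temp = math.nan if 1.0 <= t < 2.0 else 42.5
                k = int(t * 3)
                return uniform_frame(temp, timestamp=k / 3.0)

        record = run_loop(CFG, GlitchSource(), NullSink(), 3.0)
        faulted = record.data[record.data["fault"]]
        assert len(faulted) > 0
        before = record.data.iloc[faulted.index[0] - 1]
        assert np.all(faulted["output_percent"] == before["output_percent"])

    def test_commands_logged_every_tick_at_loop_cadence(self):
        sink = NullSink()
        record = run_loop(CFG, ConstantFrameSource(40.0), sink, 7.0)
        assert len(sink.commands) == len(record) == 20
        np.testing.assert_allclose(np.diff(record.times), CFG.loop_period)
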