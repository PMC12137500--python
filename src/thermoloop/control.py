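"""The temperature-feedback control algorithm.

The controller runs a ~350 ms loop on the latest available sensor frame
(zero-order hold) and regulates the centre-average temperature against a
target.  Two mechanisms come from the device firmware this module models:

1. **Sample discrimination.**  Samples with strong optical absorption (liver)
   heat much faster than weakly absorbing phantoms (agar).  The first and the
   five-second centre-average readings are recorded; if the rise exceeds
   5 degC the gain coefficient ``g`` stays at its fast-sample value (0),
   otherwise it is set to the slow-sample value (30).  The comparison is
   strict: a rise of exactly 5 degC selects the slow-sample gain.

2. **Proportional law with threshold overrides.**  With signed error
   ``diff = measured - target``:

   - ``diff < -1.0`` degC  -> drive at 100 % (3 W at full scale);
   - ``diff > +0.6`` degC  -> drive reduced to a configurable floor
     (default 0 %, laser off);
   - otherwise             -> ``output % = (50 + g) - diff * (50 - g)``,
     clamped to [0, 100].

   The law is continuous at the lower band edge: at ``diff = -1`` the
   formula evaluates to 100 for any ``g``.

Percent output maps linearly to optical power (100 % = max power, default
3 W) and affinely to drive current between a threshold current and the
full-scale current, standing in for the diode's current-power calibration
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SensorFault, TimingError
from .ir_array import SensorFrame, center_average
from .records import RunRecord

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ControlCommand",
    "LaserCalibration",
    "classify_sample",
    "control_step",
    "run_loop",
    "FrameSource",
    "CommandSink",
]

# absorbs float representation error at the band edges (e.g. 43.1 - 42.5);
# ties at a threshold stay in the proportional branch, as specified
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class ControllerConfig:
    """Targets, thresholds and timing of the control loop."""

    target_temp: float
    low_threshold: float = -1.0       # degC, relative to target
    high_threshold: float = 0.6       # degC, relative to target
    discrimination_window: float = 5.0  # s
    discrimination_delta: float = 5.0   # degC
    g_fast: float = 0.0
    g_slow: float = 30.0
    loop_period: float = 0.350        # s
    max_power: float = 3.0            # W
    floor_percent: float = 0.0        # drive above the high threshold

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ConfigurationError("low_threshold must be < high_threshold")
        for g in (self.g_fast, self.g_slow):
            if not (0.0 <= g <= 50.0):
                raise ConfigurationError("g coefficients must lie in [0, 50]")
        if self.loop_period <= 0:
            raise ConfigurationError("loop_period must be > 0")
        if not (0.0 <= self.floor_percent <= 100.0):
            raise ConfigurationError("floor_percent must lie in [0, 100]")


@dataclass
class ControllerState:
    """Phase and discrimination anchors of a running controller."""

    phase: str = "idle"               # idle | discriminating | running
    g_coefficient: float = 0.0
    t0_temp: float = math.nan
    t5_temp: float = math.nan
    last_output_percent: float = 0.0


@dataclass(frozen=True)
class ControlCommand:
    timestamp: float
    output_percent: float
    power: float
    current: float


@dataclass(frozen=True)
class LaserCalibration:
    """Parametric stand-in for the diode's current-power curve.

    Power is linear in percent (100 % = ``max_power``); current is affine in
    power between the lasing threshold ``i_threshold`` and the full-scale
    ``i_max``.  Both maps are invertible on their range.
    """

    max_power: float = 3.0
    i_threshold: float = 0.5
    i_max: float = 3.5

    def percent_to_power(self, percent: float) -> float:
        if not (0.0 <= percent <= 100.0):
            raise ConfigurationError(f"percent {percent} outside [0, 100]")
        return self.max_power * percent / 100.0

    def power_to_percent(self, power: float) -> float:
        if not (0.0 <= power <= self.max_power * (1 + 1e-12)):
            raise ConfigurationError(f"power {power} outside [0, {self.max_power}]")
        return 100.0 * power / self.max_power

    def power_to_current(self, power: float) -> float:
        if not (0.0 <= power <= self.max_power * (1 + 1e-12)):
            raise ConfigurationError(f"power {power} outside [0, {self.max_power}]")
        return self.i_threshold + (self.i_max - self.i_threshold) * power / self.max_power

    def current_to_power(self, current: float) -> float:
        return (current - self.i_threshold) / (self.i_max - self.i_threshold) * self.max_power


def classify_sample(t0_temp: float, t5_temp: float, config: ControllerConfig) -> float:
    """Select the gain coefficient from the five-second temperature rise.

    A rise strictly greater than ``discrimination_delta`` marks a
    fast-heating (strongly absorbing) sample and keeps ``g_fast``; anything
    else selects ``g_slow``.
    """
    if not (math.isfinite(t0_temp) and math.isfinite(t5_temp)):
        raise SensorFault("discrimination anchors must be finite")
    rise = t5_temp - t0_temp
    return config.g_fast if rise > config.discrimination_delta else config.g_slow


def control_step(
    measured_temp: float, config: ControllerConfig, g_coefficient: float
) -> float:
    """One evaluation of the threshold-plus-proportional law; returns percent."""
    if not math.isfinite(measured_temp):
        raise SensorFault(f"non-finite measurement {measured_temp}")
    diff = measured_temp - config.target_temp
    if diff < config.low_threshold - _EDGE_TOL:
        return 100.0
    if diff > config.high_threshold + _EDGE_TOL:
        return float(config.floor_percent)
    raw = (50.0 + g_coefficient) - diff * (50.0 - g_coefficient)
    return float(np.clip(raw, 0.0, 100.0))


class FrameSource(Protocol):
    def latest_frame(self, t: float) -> SensorFrame | None: ...


class CommandSink(Protocol):
    def apply(self, command: ControlCommand) -> None: ...


def run_loop(
    config: ControllerConfig,
    frame_source: FrameSource,
    command_sink: CommandSink,
    duration: float,
    calibration: LaserCalibration | None = None,
    metadata: dict | None = None,
) -> RunRecord:
    """Execute the full control loop for ``duration`` seconds.

    Ticks run at ``loop_period``; each tick reads the latest completed frame
    (zero-order hold), evaluates the law, and pushes a command to the sink.
    The first tick records the discrimination anchor ``t0``; the first tick
    at or past the discrimination window classifies the sample once and
    switches phase to ``running``.  During the window the loop drives with
    ``g_fast`` (the firmware initialises g to zero).

    A tick whose frame has not refreshed since the previous tick is flagged
    ``stale`` (the held command repeats).  A non-finite reading holds the
    previous command and flags ``fault``.
    """
    if duration < 0:
        raise ConfigurationError("duration must be >= 0")
    cal = calibration or LaserCalibration(max_power=config.max_power)
    state = ControllerState(phase="idle", g_coefficient=config.g_fast)
    rows: list[dict] = []
    prev_frame_time: float | None = None

    # ticks at k * loop_period for every k with t strictly inside [0, duration)
    n_ticks = math.floor(duration / config.loop_period - 1e-9) + 1 if duration > 0 else 0
    for k in range(n_ticks):
        t = k * config.loop_period
        frame = frame_source.latest_frame(t)
        if frame is None:
            if k == 0:
                raise TimingError("no sensor frame available at loop start")
            stale = True
            measured = rows[-1]["frame_temp_C"]
            frame_time = prev_frame_time
        else:
            stale = prev_frame_time is not None and frame.timestamp == prev_frame_time
            measured = center_average(frame)
            frame_time = frame.timestamp
            prev_frame_time = frame.timestamp

        if k == 0:
            state.phase = "discriminating"
            state.t0_temp = measured
        if state.phase == "discriminating" and t >= config.discrimination_window:
            state.t5_temp = measured
            state.g_coefficient = classify_sample(state.t0_temp, state.t5_temp, config)
            state.phase = "running"

        fault = not math.isfinite(measured)
        if fault:
            percent = state.last_output_percent
        else:
            percent = control_step(measured, config, state.g_coefficient)
            state.last_output_percent = percent

        power = cal.percent_to_power(percent)
        current = cal.power_to_current(power)
        command_sink.apply(
            ControlCommand(timestamp=t, output_percent=percent, power=power, current=current)
        )
        rows.append(
            {
                "time_s": t,
                "frame_time_s": frame_time,
                "frame_temp_C": measured,
                "output_percent": percent,
                "power_W": power,
                "current_A": current,
                "g_coefficient": state.g_coefficient,
                "phase": state.phase,
                "stale": stale,
                "fault": fault,
            }
        )

    meta = dict(metadata or {})
    meta.setdefault("target_temp_C", config.target_temp)
    meta.setdefault("loop_period_s", config.loop_period)
    meta.setdefault("duration_s", duration)
    columns = [
        "time_s", "frame_time_s", "frame_temp_C", "output_percent",
        "power_W", "current_A", "g_coefficient", "phase", "stale", "fault",
    ]
    return RunRecord(data=pd.DataFrame(rows, columns=columns), metadata=meta)
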