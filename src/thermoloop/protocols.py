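"""End-to-end experiment protocols.

Couples the bioheat solver, the virtual IR array and the controller into the
two experiment types the rig was evaluated with:

- **temperature-controlled irradiation**: the full closed loop
  (discrimination, then the proportional law) holds the sample at a target
  temperature (42.5, 50, 60 or 70 degC), typically for 300 s and in three
  replicates;
- **fixed-power irradiation**: the drive current is fixed at the time
  average of a paired controlled run (integrate the current trace, divide by
  the duration, invert the calibration) and held for the same duration —
  the open-loop contrast that shows why feedback is needed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict

import numpy as np

from .bioheat import Beam, Material, ThermalField, deposit_energy, surface_temperature
from .control import (
    ControlCommand,
    ControllerConfig,
    LaserCalibration,
    run_loop,
)
from .errors import ConfigurationError
from .ir_array import SensorConfig, SensorFrame, capture_frame, center_average
from .records import RunRecord

__all__ = [
    "SimulatedRig",
    "run_temperature_controlled",
    "run_fixed_power",
    "run_replicates",
    "equivalent_fixed_current",
    "equivalent_fixed_power",
]


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class SimulatedRig:
    """Virtual bench: slab + beam + IR array, advanced on demand.

    Implements both controller-side interfaces: it is a *frame source*
    (``latest_frame(t)`` advances the physics to ``t``, capturing frames at
    the sensor cadence along the way, and returns the newest one) and a
    *command sink* (``apply`` changes the beam power from the command's
    timestamp onward — the actuation side of the zero-order hold).

    Sensor noise is drawn from a dedicated generator seeded per run, so a
    run is bit-reproducible given its seed.
    """

    def __init__(
        self,
        material: Material,
        *,
        beam: Beam | None = None,
        sensor: SensorConfig | None = None,
        nr: int = 64,
        nz: int = 32,
        radius: float = 0.02,
        ambient: float = 25.0,
        h: float = 10.0,
        initial_temp: float | None = None,
        seed: int = 0,
        record_frames: bool = False,
    ) -> None:
        self.material = material
        self.beam = beam or Beam(power=0.0)
        self.sensor = sensor or SensorConfig()
        self.field = ThermalField(
            material,
            nr=nr,
            nz=nz,
            radius=radius,
            ambient=ambient,
            h=h,
            initial_temp=initial_temp,
        )
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.record_frames = record_frames
        self.frames: list[SensorFrame] = []
        self.power = 0.0
        # the source map is linear in power: precompute at unit power
        ref = Beam(
            power=1.0,
            spot_area=self.beam.spot_area,
            profile=self.beam.profile,
            max_power=self.beam.max_power,
        )
        self._unit_source = deposit_energy(self.field, material, ref)
        self._next_frame_time = 0.0
        self._latest: SensorFrame | None = None

    # -- frame source ---------------------------------------------------
    def latest_frame(self, t: float) -> SensorFrame | None:
        self.advance_to(t)
        return self._latest

    def advance_to(self, t: float) -> None:
        """Advance the physics to time ``t``, emitting frames on the way."""
        period = self.sensor.frame_period
        while self._next_frame_time <= t + 1e-9:
            ft = self._next_frame_time
            dt = ft - self.field.time
            if dt > 1e-12:
                self.field.advance(self._unit_source * self.power, dt)
            frame = capture_frame(
                surface_temperature(self.field), self.sensor, self.rng, timestamp=ft
            )
            self._latest = frame
            if self.record_frames:
                self.frames.append(frame)
            self._next_frame_time = ft + period
        if t - self.field.time > 1e-12:
            self.field.advance(self._unit_source * self.power, t - self.field.time)

    # -- command sink ---------------------------------------------------
    def apply(self, command: ControlCommand) -> None:
        self.advance_to(command.timestamp)
        self.power = command.power


def _run_metadata(material: Material, rig: SimulatedRig, extra: dict) -> dict:
    cfg = {
        "material": asdict(material),
        "sensor": asdict(rig.sensor),
        "beam_spot_area_cm2": rig.beam.spot_area,
        "grid": {"nr": rig.field.nr, "nz": rig.field.nz, "radius_m": rig.field.radius},
        "ambient_C": rig.field.ambient,
        "h_W_m2K": rig.field.h,
        **extra,
    }
    meta = {"material": material.name, "seed": rig.seed, **extra}
    meta["config_hash"] = _config_hash(cfg)
    return meta


def run_temperature_controlled(
    material: Material,
    target: float,
    duration: float = 300.0,
    seed: int = 0,
    *,
    controller: ControllerConfig | None = None,
    calibration: LaserCalibration | None = None,
    rig_kwargs: dict | None = None,
    return_rig: bool = False,
):
    """Full closed-loop run: discrimination, then proportional control.

    Returns the :class:`RunRecord` (and the rig, if ``return_rig``).
    """
    config = controller or ControllerConfig(target_temp=target)
    if duration <= config.discrimination_window:
        raise ConfigurationError("duration must exceed the discrimination window")
    rig = SimulatedRig(material, seed=seed, **(rig_kwargs or {}))
    meta = _run_metadata(
        material, rig, {"protocol": "temperature_controlled", "target_C": target}
    )
    record = run_loop(config, rig, rig, duration, calibration=calibration, metadata=meta)
    return (record, rig) if return_rig else record


def run_fixed_power(
    material: Material,
    power: float,
    duration: float = 300.0,
    seed: int = 0,
    *,
    loop_period: float = 0.350,
    max_power: float = 3.0,
    calibration: LaserCalibration | None = None,
    rig_kwargs: dict | None = None,
    return_rig: bool = False,
):
    """Open-loop run at constant power; readings logged at the loop cadence."""
    if not (0.0 <= power <= max_power):
        raise ConfigurationError(f"power {power} W outside [0, {max_power}] W")
    cal = calibration or LaserCalibration(max_power=max_power)
    rig = SimulatedRig(material, seed=seed, **(rig_kwargs or {}))
    rig.power = power
    percent = cal.power_to_percent(power)
    current = cal.power_to_current(power)

    rows = []
    n_ticks = math.floor(duration / loop_period - 1e-9) + 1 if duration > 0 else 0
    prev_ft = None
    for k in range(n_ticks):
        t = k * loop_period
        frame = rig.latest_frame(t)
        stale = prev_ft is not None and frame.timestamp == prev_ft
        prev_ft = frame.timestamp
        rows.append(
            {
                "time_s": t,
                "frame_time_s": frame.timestamp,
                "frame_temp_C": center_average(frame),
                "output_percent": percent,
                "power_W": power,
                "current_A": current,
                "g_coefficient": math.nan,
                "phase": "fixed",
                "stale": stale,
                "fault": False,
            }
        )
    import pandas as pd

    meta = _run_metadata(material, rig, {"protocol": "fixed_power", "power_W": power})
    meta["duration_s"] = duration
    record = RunRecord(data=pd.DataFrame(rows), metadata=meta)
    return (record, rig) if return_rig else record


def run_replicates(
    kind: str = "controlled",
    n: int = 3,
    base_seed: int = 0,
    **kwargs,
) -> list[RunRecord]:
    """Repeat a protocol ``n`` times with distinct seeds (base_seed + index)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    runner = {"controlled": run_temperature_controlled, "fixed": run_fixed_power}.get(kind)
    if runner is None:
        raise ConfigurationError(f"unknown protocol kind {kind!r}")
    out = []
    for i in range(n):
        rec = runner(seed=base_seed + i, **kwargs)
        rec.metadata["replicate"] = i
        out.append(rec)
    return out


def equivalent_fixed_current(record: RunRecord) -> float:
    """Time average of the current trace: integrate, divide by the duration.

    This is how the fixed-power drive of the contrast experiment is chosen
    from its paired temperature-controlled run.
    """
    t = record.times
    if len(t) < 2 or t[-1] - t[0] <= 0:
        raise ConfigurationError("record must span a non-zero duration")
    return float(np.trapezoid(record.currents, t) / (t[-1] - t[0]))


def equivalent_fixed_power(
    record: RunRecord, calibration: LaserCalibration | None = None
) -> float:
    """Power corresponding to the time-averaged current, via the inverse calibration."""
    cal = calibration or LaserCalibration()
    return cal.current_to_power(equivalent_fixed_current(record))
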