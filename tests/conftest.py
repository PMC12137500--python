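import numpy as np
import pytest
from hypothesis import settings

from thermoloop import (
    SensorFrame,
    get_material,
    run_fixed_power,
    run_temperature_controlled,
)
from thermoloop.protocols import equivalent_fixed_power

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def liver():
    return get_material("liver")


@pytest.fixture(scope="session")
def agar():
    return get_material("agar")


@pytest.fixture(scope="session")
def controlled_liver_run(liver):
    """Full 300 s closed-loop run at 42.5 °C, with the rig (frames recorded)."""
    return run_temperature_controlled(
        liver, 42.5, 300.0, seed=1, rig_kwargs={"record_frames": True}, return_rig=True
    )


@pytest.fixture(scope="session")
def paired_fixed_run(liver, controlled_liver_run):
    """Open-loop run at the time-averaged power of the controlled run."""
    record, _ = controlled_liver_run
    power = equivalent_fixed_power(record)
    return run_fixed_power(liver, power, 300.0, seed=101), power


def uniform_frame(temp: float, timestamp: float = 0.0) -> SensorFrame:
    return SensorFrame(timestamp=timestamp, pixels=np.full((32, 32), float(temp)))


class ConstantFrameSource:
    """Uniform-temperature frames at the sensor cadence (test double)."""

    def __init__(self, temp: float, frame_period: float = 1.0 / 3.0):
        self.temp = temp
        self.period = frame_period

    def latest_frame(self, t: float):
        if t < 0:
            return None
        k = int(np.floor(t / self.period + 1e-9))
        return uniform_frame(self.temp, timestamp=k * self.period)


class NullSink:
    def __init__(self):
        self.commands = []

    def apply(self, cmd):
        self.commands.append(cmd)
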