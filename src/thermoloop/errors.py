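"""Exception hierarchy for the testbed."""


class ThermoloopError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThermoloopError):
    """Invalid material, beam, sensor or controller configuration."""


class StabilityError(ThermoloopError):
    """Explicit time step exceeds the diffusion stability bound."""


class GeometryError(ThermoloopError):
    """Sensor footprint (or other geometry) falls outside the simulated domain."""


class TimingError(ThermoloopError):
    """Control loop started without a frame, or event times are inconsistent."""


class SensorFault(ThermoloopError):
    """A frame delivered a non-finite temperature reading."""


class RunFormatError(ThermoloopError):
    """A run log file is malformed or missing required columns."""
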