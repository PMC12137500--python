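"""Virtual 32x32 thermopile IR array.

Emulates the low-cost IR array used for non-contact temperature feedback: a
32x32 pixel sensor mounted 25 mm above the sample with a ~33 degree field of
view, read out at 3 Hz (the hardware supports 2-27 Hz).  Each pixel reports
the area-average surface temperature in its footprint cell plus independent
Gaussian read noise.  The controller consumes the mean of the four central
pixels — the 2x2 block at 0-based indices (15, 15)..(16, 16), i.e. rows and
columns 16-17 when counting from 1 — which the operator aligns with the
laser spot so it reads the peak of the heating zone.

The sensor's 49-degree mounting angle is ignored: the footprint is modelled
as a square of side 2*d*tan(FOV/2) (~14.8 mm) centred on the beam axis, and
no emissivity model is applied (the hardware ran factory-calibrated).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import math
import numpy as np
import pandas as pd

from .bioheat import SurfaceMap
from .errors import ConfigurationError, GeometryError

__all__ = [
    "SensorConfig",
    "SensorFrame",
    "capture_frame",
    "center_average",
    "ReplayFrameSource",
    "write_frames",
    "read_frames",
]

RESOLUTION = 32


@dataclass(frozen=True)
class SensorConfig:
    """Geometry, timing and noise of the virtual array."""

    frame_rate: float = 3.0     # Hz; hardware range 2-27
    distance: float = 0.025     # m from the sample
    fov: float = 33.0           # degrees, full angle
    noise_sd: float = 0.1       # degC per pixel, Gaussian
    resolution: int = RESOLUTION
    subsamples: int = 3         # sub-grid per pixel for area averaging

    def __post_init__(self) -> None:
        if self.resolution != RESOLUTION:
            raise ConfigurationError("the array is fixed at 32x32 pixels")
        if not (2.0 <= self.frame_rate <= 27.0):
            raise ConfigurationError("frame_rate must lie in [2, 27] Hz")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.distance <= 0 or not (0 < self.fov < 180):
            raise ConfigurationError("invalid sensor geometry")
        if self.subsamples < 1:
            raise ConfigurationError("subsamples must be >= 1")

    @property
    def footprint_side(self) -> float:
        """Side of the square surface patch imaged by the array, m."""
        return 2.0 * self.distance * math.tan(math.radians(self.fov) / 2.0)

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class SensorFrame:
    """One 32x32 temperature image with its capture time."""

    timestamp: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != (RESOLUTION, RESOLUTION):
            raise ConfigurationError("frame must be 32x32")


def _pixel_sample_radii(config: SensorConfig) -> np.ndarray:
    """Radii of the sub-sample points, shape (32, s, 32, s)."""
    n, s = config.resolution, config.subsamples
    side = config.footprint_side
    px = side / n
    centers = (np.arange(n) + 0.5) * px - side / 2.0
    offs = ((np.arange(s) + 0.5) / s - 0.5) * px
    coords = centers[:, None] + offs[None, :]          # (n, s)
    flat = coords.reshape(-1)                           # (n*s,)
    xx, yy = np.meshgrid(flat, flat, indexing="xy")
    return np.hypot(xx, yy).reshape(n, s, n, s)


def capture_frame(
    surface: SurfaceMap,
    config: SensorConfig,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> SensorFrame:
    """Image the surface: per-pixel area average plus Gaussian read noise.

    Raises :class:`GeometryError` if the footprint (corner to corner)
    extends beyond the simulated surface.
    """
    corner = config.footprint_side / math.sqrt(2.0)
    if corner > surface.radius * (1 + 1e-12):
        raise GeometryError(
            f"sensor footprint (corner radius {corner * 1e3:.1f} mm) exceeds the "
            f"simulated surface (radius {surface.radius * 1e3:.1f} mm)"
        )
    radii = _pixel_sample_radii(config)
    pixels = surface.sample_r(radii).mean(axis=(1, 3))
    if config.noise_sd > 0:
        if rng is None:
            raise ConfigurationError("noise_sd > 0 requires a seeded rng stream")
        pixels = pixels + rng.normal(0.0, config.noise_sd, pixels.shape)
    return SensorFrame(timestamp=timestamp, pixels=pixels)


def center_average(frame: SensorFrame) -> float:
    """Mean of the four central pixels — the controller's process variable."""
    return float(frame.pixels[15:17, 15:17].mean())


class ReplayFrameSource:
    """Frame source backed by a list of recorded frames (e.g. a CSV log).

    ``latest_frame(t)`` returns the most recent frame with timestamp <= t,
    which is exactly the zero-order-hold contract the controller expects.
    """

    def __init__(self, frames: list[SensorFrame]):
        self.frames = sorted(frames, key=lambda f: f.timestamp)
        self._times = [f.timestamp for f in self.frames]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReplayFrameSource":
        return cls(read_frames(path))

    def latest_frame(self, t: float) -> SensorFrame | None:
        i = bisect_right(self._times, t + 1e-12)
        return self.frames[i - 1] if i else None


def write_frames(frames: list[SensorFrame], path: str | Path) -> None:
    """Log frames as CSV: time_s followed by 1024 pixel columns (row-major)."""
    cols = [f"p{i:04d}" for i in range(RESOLUTION * RESOLUTION)]
    df = pd.DataFrame(
        [f.pixels.reshape(-1) for f in frames], columns=cols
    )
    df.insert(0, "time_s", [f.timestamp for f in frames])
    df.to_csv(path, index=False)


def read_frames(path: str | Path) -> list[SensorFrame]:
    # round_trip parsing keeps replayed frames bit-identical to the originals
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [f"p{i:04d}" for i in range(RESOLUTION * RESOLUTION)]
    missing = [c for c in ["time_s", *cols] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"frame log missing columns: {missing[:3]}...")
    return [
        SensorFrame(
            timestamp=float(row["time_s"]),
            pixels=row[cols].to_numpy(dtype=float).reshape(RESOLUTION, RESOLUTION),
        )
        for _, row in df.iterrows()
    ]
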