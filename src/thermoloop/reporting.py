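"""Summary statistics, Arrhenius thermal damage, and run-log I/O.

The Arrhenius damage integral quantifies cumulative thermal injury:

    Omega(t) = integral_0^t A * exp(-Ea / (R * T(tau))) dtau

with T in kelvin, frequency factor A (1/s) and activation energy Ea
(J/mol).  At constant temperature Omega grows exactly linearly in time; a
linearly rising temperature makes the integrand grow exponentially, so
Omega is convex — the quantitative argument for temperature-controlled over
fixed-power irradiation.  Omega = 1 conventionally marks the damage
threshold.

Parameter presets (both widely used in photothermal modelling literature):
``henriques-skin`` A = 3.1e98 1/s, Ea = 6.28e5 J/mol; ``liver``
A = 7.39e39 1/s, Ea = 2.577e5 J/mol.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, RunFormatError
from .records import REQUIRED_COLUMNS, SCHEMA_VERSION, RunRecord

__all__ = [
    "RunSummary",
    "summarize",
    "arrhenius_damage",
    "ARRHENIUS_PRESETS",
    "read_run",
    "write_run",
    "plot_run",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
ZERO_C_IN_K = 273.15

ARRHENIUS_PRESETS: dict[str, tuple[float, float]] = {
    "henriques-skin": (3.1e98, 6.28e5),
    "liver": (7.39e39, 2.577e5),
}


@dataclass(frozen=True)
class RunSummary:
    """Temperature statistics over an analysis window (box-plot quantities)."""

    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n_samples: int
    window: tuple[float, float]
    damage_omega: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(record: RunRecord, window: tuple[float, float] | None = None) -> RunSummary:
    """Mean, sample sd, extrema and quartiles of the temperature trace.

    ``window`` is (t_start, t_end) in seconds; by default the final
    two-thirds of the run, which skips the heat-up ramp.  Quartiles use the
    linear-interpolation convention.
    """
    t = record.times
    if len(t) == 0:
        raise ConfigurationError("empty record")
    if window is None:
        window = (t[0] + (t[-1] - t[0]) / 3.0, t[-1])
    lo, hi = window
    if hi <= lo:
        raise ConfigurationError(f"empty window {window}")
    rows = record.window(lo, hi)
    if len(rows) == 0:
        raise ConfigurationError(f"window {window} contains no samples")
    x = rows["frame_temp_C"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return RunSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(x.max()),
        n_samples=len(x),
        window=(float(lo), float(hi)),
    )


def arrhenius_damage(
    record_or_temps: RunRecord | np.ndarray,
    A: float | None = None,
    Ea: float | None = None,
    *,
    times: np.ndarray | None = None,
    preset: str | None = None,
) -> np.ndarray:
    """Cumulative damage integral Omega(t) along the temperature trace.

    Accepts either a :class:`RunRecord` or explicit ``temps``/``times``
    arrays (degC / s).  Integration is trapezoidal; Omega[0] = 0 and Omega
    is non-decreasing.
    """
    if preset is not None:
        try:
            A, Ea = ARRHENIUS_PRESETS[preset]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {preset!r}; have {sorted(ARRHENIUS_PRESETS)}"
            ) from None
    if A is None or Ea is None or A <= 0 or Ea <= 0:
        raise ConfigurationError("A and Ea must be positive (or give a preset)")
    if isinstance(record_or_temps, RunRecord):
        temps = record_or_temps.temperatures
        times = record_or_temps.times
    else:
        temps = np.asarray(record_or_temps, dtype=float)
        if times is None:
            raise ConfigurationError("times required with a bare temperature array")
        times = np.asarray(times, dtype=float)
    if temps.shape != times.shape or temps.ndim != 1 or len(temps) < 2:
        raise ConfigurationError("need matching 1-D times/temps with >= 2 points")
    if np.any(temps <= -ZERO_C_IN_K):
        raise ConfigurationError("non-physical temperature at or below absolute zero")
    rate = A * np.exp(-Ea / (GAS_CONSTANT * (temps + ZERO_C_IN_K)))
    return cumulative_trapezoid(rate, times, initial=0.0)


# ----------------------------------------------------------------- I/O
def write_run(record: RunRecord, csv_path: str | Path) -> Path:
    """Write a run as CSV plus a JSON metadata sidecar (same stem)."""
    csv_path = Path(csv_path)
    record.data.to_csv(csv_path, index=False)
    meta = dict(record.metadata)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta_path = csv_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return csv_path


def read_run(csv_path: str | Path) -> RunRecord:
    """Read a run log; lossless round-trip with :func:`write_run`.

    Extra columns are preserved; missing required columns raise
    :class:`RunFormatError`, as do unparseable rows (with the line number).
    """
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise RunFormatError(f"{csv_path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RunFormatError(f"{csv_path}: missing required columns {missing}")
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise RunFormatError(
                f"{csv_path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    meta_path = csv_path.with_suffix(".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return RunRecord(data=df, metadata=metadata)


def plot_run(record: RunRecord, path: str | Path | None = None):
    """Dual-axis plot: temperature (left) and drive current (right) vs time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(record.times, record.temperatures, color="tab:red", lw=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("centre-average temperature (°C)", color="tab:red")
    ax2 = ax.twinx()
    ax2.plot(record.times, record.currents, color="tab:blue", lw=0.8, alpha=0.7)
    ax2.set_ylabel("drive current (A)", color="tab:blue")
    target = record.metadata.get("target_C")
    if target is not None:
        ax.axhline(target, color="k", ls="--", lw=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
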