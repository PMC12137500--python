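"""Run logs: the per-tick record every experiment produces.

A :class:`RunRecord` is a thin wrapper around a pandas DataFrame (one row
per controller tick) plus a metadata dict describing the run (material,
target or fixed power, seed, configuration hash, schema version).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: Columns every run log must carry (extra columns are preserved on I/O).
REQUIRED_COLUMNS = [
    "time_s",
    "frame_time_s",
    "frame_temp_C",
    "output_percent",
    "power_W",
    "current_A",
]

OPTIONAL_COLUMNS = ["g_coefficient", "phase", "stale", "fault"]


@dataclass
class RunRecord:
    """Time-stamped log of one irradiation run."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("schema_version", SCHEMA_VERSION)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        """Center-average temperature trace, degC."""
        return self.data["frame_temp_C"].to_numpy(dtype=float)

    @property
    def currents(self) -> np.ndarray:
        return self.data["current_A"].to_numpy(dtype=float)

    @property
    def powers(self) -> np.ndarray:
        return self.data["power_W"].to_numpy(dtype=float)

    def window(self, t_start: float, t_end: float) -> pd.DataFrame:
        """Rows with t_start <= time_s <= t_end."""
        t = self.data["time_s"]
        return self.data[(t >= t_start) & (t <= t_end)]
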