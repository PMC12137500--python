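"""Material presets and YAML configuration.

Two reference samples mirror the bench experiments:

- ``agar``: weakly absorbing phantom, mu_a = 0.15 1/cm (quoted as below
  0.20 1/cm at 808 nm); water-like thermal constants.
- ``liver``: strongly absorbing tissue, mu_a = 0.90 1/cm (midpoint of the
  0.80-0.99 1/cm range reported for porcine and rat liver at 808 nm);
  literature-typical thermal constants.

The thermal constants are not measured by the bench study; they are
configurable and logged with every run.  A YAML file can override any
material, sensor or controller field, e.g.::

    materials:
      liver:
        mu_a: 0.99
        c: 3500
    controller:
      floor_percent: 10
    sensor:
      noise_sd: 0.05
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .bioheat import Material
from .control import ControllerConfig
from .errors import ConfigurationError
from .ir_array import SensorConfig

__all__ = ["MATERIALS", "get_material", "load_config"]

MATERIALS: dict[str, Material] = {
    "agar": Material(name="agar", mu_a=0.15, k=0.60, rho=1000.0, c=4186.0, thickness=0.005),
    "liver": Material(name="liver", mu_a=0.90, k=0.52, rho=1060.0, c=3600.0, thickness=0.0065),
}


def get_material(name: str, overrides: dict | None = None) -> Material:
    try:
        mat = MATERIALS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown material {name!r}; presets: {sorted(MATERIALS)}"
        ) from None
    return replace(mat, **overrides) if overrides else mat


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into ready objects.

    Returns a dict with keys ``materials`` (name -> Material), ``sensor``
    (SensorConfig or None) and ``controller`` (kwargs dict merged into
    ControllerConfig at run time, since the target comes from the CLI).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    materials = dict(MATERIALS)
    for name, fields in (raw.get("materials") or {}).items():
        if name in materials:
            materials[name] = replace(materials[name], **fields)
        else:
            materials[name] = Material(name=name, **fields)
    sensor = SensorConfig(**raw["sensor"]) if "sensor" in raw else None
    controller = raw.get("controller") or {}
    ControllerConfig(target_temp=42.5, **controller)  # validate early
    return {"materials": materials, "sensor": sensor, "controller": controller}
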