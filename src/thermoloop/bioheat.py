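"""Axisymmetric finite-volume heat solver for laser-heated sample slabs.

The sample is an ex vivo slab (agar phantom or liver tissue), so the heat
equation carries no perfusion and no metabolic term:

    rho * c * dT/dt = k * laplacian(T) + Q(r, z)

on a 2-D axisymmetric r-z grid.  The laser source Q follows the Beer-Lambert
law: a beam of power P and spot area A deposits

    Q(r, z) = mu_a * I0 * exp(-mu_a * z)        (inside the spot, flat-top)

with I0 = P / A and mu_a the absorption coefficient.  Scattering is ignored;
the samples are characterised by their absorption coefficient alone, which
means the model under-counts the fluence build-up that backscattering
produces near the surface of turbid tissue (see docs/methods.md).

The discretisation is cell-centred finite volume, which makes the scheme
exactly conservative: with insulated boundaries and no source, the volume
integral of rho*c*T is preserved to round-off at every step.  Time stepping
is explicit Euler with the step chosen from the per-cell stability bound and
sub-stepped so that sensor/controller event times are hit exactly.

Units: SI internally (m, s, W, kg); temperatures in degC; absorption
coefficients are accepted in 1/cm at the interface (the unit papers quote)
and converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, StabilityError

__all__ = [
    "Material",
    "Beam",
    "ThermalField",
    "SurfaceMap",
    "deposit_energy",
    "step",
    "surface_temperature",
]


@dataclass(frozen=True)
class Material:
    """Optical and thermal properties of a sample slab.

    Parameters
    ----------
    mu_a : absorption coefficient at the laser wavelength, 1/cm.
    k : thermal conductivity, W/(m K).
    rho : density, kg/m^3.
    c : specific heat, J/(kg K).
    thickness : slab thickness, m.
    """

    name: str
    mu_a: float
    k: float
    rho: float
    c: float
    thickness: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ConfigurationError(f"mu_a must be >= 0, got {self.mu_a}")
        for attr in ("k", "rho", "c", "thickness"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(
                    f"{attr} must be > 0, got {getattr(self, attr)}"
                )

    @property
    def mu_a_si(self) -> float:
        """Absorption coefficient in 1/m."""
        return self.mu_a * 100.0

    @property
    def alpha(self) -> float:
        """Thermal diffusivity k/(rho*c), m^2/s."""
        return self.k / (self.rho * self.c)


@dataclass(frozen=True)
class Beam:
    """Laser beam: power in W, spot area in cm^2 (the unit quoted for the rig).

    ``flat_top`` spreads the power uniformly over the spot; ``gaussian`` uses
    irradiance I(r) = I0*exp(-2 r^2 / w^2) with w chosen so the effective area
    pi*w^2/2 equals ``spot_area``.
    """

    power: float
    spot_area: float = 0.85
    profile: str = "flat_top"
    max_power: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.power <= self.max_power):
            raise ConfigurationError(
                f"beam power {self.power} W outside [0, {self.max_power}] W"
            )
        if self.spot_area <= 0:
            raise ConfigurationError("spot_area must be > 0")
        if self.profile not in ("flat_top", "gaussian"):
            raise ConfigurationError(f"unknown beam profile {self.profile!r}")

    @property
    def spot_area_si(self) -> float:
        """Spot area in m^2."""
        return self.spot_area * 1e-4

    @property
    def spot_radius(self) -> float:
        """Flat-top spot radius in m (radius of a disc of the spot area)."""
        return math.sqrt(self.spot_area_si / math.pi)


@dataclass
class SurfaceMap:
    """Top-layer temperature profile, sampled radially.

    ``values[i]`` is the temperature of the top-layer cell centred at
    ``r[i]``; ``radius`` is the extent of the simulated surface.  Sampling at
    arbitrary (x, y) interpolates linearly in radius (constant inside the
    innermost cell centre).
    """

    r: np.ndarray
    values: np.ndarray
    radius: float

    def sample_r(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.r, self.values)

    def sample_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.sample_r(np.hypot(x, y))

    def max(self) -> float:
        return float(self.values.max())


class ThermalField:
    """Temperature state of the slab on a cell-centred axisymmetric grid.

    Cells are indexed ``T[j, i]`` with ``j`` the axial (depth) index, ``j=0``
    at the irradiated surface, and ``i`` the radial index, ``i=0`` at the
    axis.  Boundary conditions:

    - ``top``: ``"convective"`` (heat transfer coefficient ``h`` to ambient),
      ``"insulated"``, or ``"flux"`` (uniform imposed flux ``top_flux`` W/m^2
      into the sample — used for validation against the analytic
      constant-flux conduction solution);
    - ``side``, ``bottom``: ``"dirichlet"`` (held at ambient) or
      ``"insulated"``.
    """

    def __init__(
        self,
        material: Material,
        *,
        nr: int = 64,
        nz: int = 32,
        radius: float = 0.02,
        ambient: float = 25.0,
        h: float = 10.0,
        initial_temp: float | None = None,
        top: str = "convective",
        side: str = "dirichlet",
        bottom: str = "dirichlet",
        top_flux: float = 0.0,
    ) -> None:
        if nr < 2 or nz < 2:
            raise ConfigurationError("grid needs at least 2x2 cells")
        if radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if h < 0:
            raise ConfigurationError("h must be >= 0")
        for name, val in (("top", top), ("side", side), ("bottom", bottom)):
            allowed = ("convective", "insulated", "flux") if name == "top" else (
                "dirichlet",
                "insulated",
            )
            if val not in allowed:
                raise ConfigurationError(f"{name} boundary {val!r} not in {allowed}")

        self.material = material
        self.nr, self.nz = nr, nz
        self.radius = radius
        self.thickness = material.thickness
        self.ambient = ambient
        self.h = h
        self.top, self.side, self.bottom = top, side, bottom
        self.top_flux = top_flux
        self.time = 0.0
        self.absorbed_J = 0.0   # cumulative source energy
        self.boundary_J = 0.0   # cumulative heat entering through boundaries

        self.dr = radius / nr
        self.dz = self.thickness / nz
        self.r_centers = (np.arange(nr) + 0.5) * self.dr
        self.z_centers = (np.arange(nz) + 0.5) * self.dz
        self.r_faces = np.arange(nr + 1) * self.dr
        self.z_faces = np.arange(nz + 1) * self.dz

        t0 = ambient if initial_temp is None else initial_temp
        self.T = np.full((nz, nr), float(t0))

        k = material.k
        # conductances G (W/K): heat flow between neighbours = G * dT
        ring_area = 2.0 * np.pi * self.r_centers * self.dr      # top/bottom face area
        self._A_top = ring_area
        self._Gr = k * 2.0 * np.pi * self.r_faces[1:-1] * self.dz / self.dr  # (nr-1,)
        self._Gz = k * ring_area / self.dz                                    # (nr,)
        self._G_side = (
            k * 2.0 * np.pi * self.radius * self.dz / (self.dr / 2.0)
            if side == "dirichlet"
            else 0.0
        )
        self._G_bot = (
            k * ring_area / (self.dz / 2.0) if bottom == "dirichlet" else np.zeros(nr)
        )
        if top == "convective" and h > 0:
            # series resistance: convection + conduction through the half-cell
            u_top = 1.0 / (1.0 / h + self.dz / (2.0 * k))
            self._G_top = u_top * ring_area
        else:
            self._G_top = np.zeros(nr)

        self._cell_vol = ring_area * self.dz                    # (nr,)
        self._rhocV = material.rho * material.c * self._cell_vol

        # stability: explicit Euler keeps the update a convex combination as
        # long as dt <= rho*c*V / (sum of adjoining conductances), per cell
        g_tot = np.zeros((nz, nr))
        g_tot[:, :-1] += self._Gr
        g_tot[:, 1:] += self._Gr
        g_tot[:, -1] += self._G_side
        g_tot[:-1, :] += self._Gz
        g_tot[1:, :] += self._Gz
        g_tot[0, :] += self._G_top
        g_tot[-1, :] += self._G_bot
        self.stable_dt = float((self._rhocV / g_tot).min())

    # ------------------------------------------------------------------
    def energy(self) -> float:
        """Volume integral of rho*c*T, J (relative to 0 degC)."""
        return float((self._rhocV * self.T).sum())

    def _euler_step(self, source: np.ndarray | None, dt: float) -> None:
        T = self.T
        Q = np.zeros_like(T)  # net heat flow into each cell, W

        fr = self._Gr * (T[:, 1:] - T[:, :-1])
        Q[:, :-1] += fr
        Q[:, 1:] -= fr
        fz = self._Gz * (T[1:, :] - T[:-1, :])
        Q[:-1, :] += fz
        Q[1:, :] -= fz

        qb = 0.0
        if self.side == "dirichlet":
            f = self._G_side * (self.ambient - T[:, -1])
            Q[:, -1] += f
            qb += f.sum()
        if self.bottom == "dirichlet":
            f = self._G_bot * (self.ambient - T[-1, :])
            Q[-1, :] += f
            qb += f.sum()
        if self.top == "convective":
            f = self._G_top * (self.ambient - T[0, :])
            Q[0, :] += f
            qb += f.sum()
        elif self.top == "flux":
            f = self.top_flux * self._A_top
            Q[0, :] += f
            qb += f.sum()

        qs = 0.0
        if source is not None:
            sv = source * self._cell_vol
            Q += sv
            qs = sv.sum()

        self.T = T + dt * Q / self._rhocV
        self.time += dt
        self.absorbed_J += qs * dt
        self.boundary_J += qb * dt

    def advance(self, source: np.ndarray | None, dt: float, safety: float = 0.9) -> None:
        """Advance by exactly ``dt`` using stable explicit sub-steps."""
        if dt < 0:
            raise ConfigurationError("dt must be >= 0")
        if dt == 0:
            return
        n = max(1, math.ceil(dt / (safety * self.stable_dt)))
        h = dt / n
        for _ in range(n):
            self._euler_step(source, h)

    def surface_values(self, extrapolate: bool = False) -> np.ndarray:
        """Top-layer temperatures; optionally extrapolated to the z=0 face."""
        t0 = self.T[0, :]
        if not extrapolate:
            return t0.copy()
        k, dz = self.material.k, self.dz
        if self.top == "flux":
            return t0 + self.top_flux * dz / (2.0 * k)
        if self.top == "convective" and self.h > 0:
            b = self.h * dz / (2.0 * k)
            return (t0 + b * self.ambient) / (1.0 + b)
        return t0.copy()


# ----------------------------------------------------------------------
def deposit_energy(field: ThermalField, material: Material, beam: Beam) -> np.ndarray:
    """Volumetric Beer-Lambert source map, W/m^3, shape (nz, nr).

    Each cell receives the exact fraction of beam power absorbed in its
    annulus x depth-interval, divided by the cell volume, so the volume
    integral of the map equals ``P * (1 - exp(-mu_a * L))`` to round-off
    (and never exceeds the beam power).
    """
    if beam.power < 0:
        raise ConfigurationError("negative beam power")
    nz, nr = field.nz, field.nr
    if beam.power == 0 or material.mu_a == 0:
        return np.zeros((nz, nr))

    mu = material.mu_a_si
    zf = field.z_faces
    frac_z = np.exp(-mu * zf[:-1]) - np.exp(-mu * zf[1:])  # absorbed per layer

    rf = field.r_faces
    if beam.profile == "flat_top":
        rs = beam.spot_radius
        inner = np.minimum(rf, rs)
        power_r = beam.power * (inner[1:] ** 2 - inner[:-1] ** 2) / rs**2
    else:  # gaussian, effective area pi w^2 / 2 = spot area
        w2 = 2.0 * beam.spot_area_si / math.pi
        g = np.exp(-2.0 * rf**2 / w2)
        power_r = beam.power * (g[:-1] - g[1:])

    absorbed = frac_z[:, None] * power_r[None, :]  # W per cell
    return absorbed / field._cell_vol[None, :]


def step(
    field: ThermalField,
    source: np.ndarray | None,
    dt: float,
    *,
    substep: bool = True,
) -> ThermalField:
    """Advance the field by ``dt`` under the given source map.

    With ``substep=True`` (the default) the step is split into explicit
    sub-steps that satisfy the stability bound.  With ``substep=False`` a
    single raw Euler step is taken and an unstable ``dt`` is rejected.
    """
    if dt < 0:
        raise ConfigurationError("dt must be >= 0")
    if substep:
        field.advance(source, dt)
    else:
        if dt > field.stable_dt:
            raise StabilityError(
                f"dt={dt:g} s exceeds the stability bound {field.stable_dt:g} s"
            )
        if dt > 0:
            field._euler_step(source, dt)
    return field


def surface_temperature(field: ThermalField) -> SurfaceMap:
    """Project the top layer into a radially-sampled surface map for the sensor."""
    return SurfaceMap(
        r=field.r_centers.copy(),
        values=field.surface_values(),
        radius=field.radius,
    )
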