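"""Solver physics: Beer-Lambert deposition, conservation, analytic oracle."""

import numpy as np
import pytest
from scipy.special import erfc

from thermoloop import Beam, Material, ThermalField, deposit_energy, step, surface_temperature
from thermoloop.errors import ConfigurationError, StabilityError


def absorbed_power(field, source):
    """Numerical quadrature of the source map over the domain, W."""
    return float((source * field._cell_vol[None, :]).sum())


class TestMaterialsAndBeams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_a": -0.1},
            {"k": 0.0},
            {"rho": -1.0},
            {"c": 0.0},
            {"thickness": 0.0},
        ],
    )
    def test_invalid_material_rejected(self, kwargs):
        base = dict(name="x", mu_a=0.9, k=0.52, rho=1060.0, c=3600.0, thickness=0.0065)
        with pytest.raises(ConfigurationError):
            Material(**{**base, **kwargs})

    def test_negative_and_excess_beam_power_rejected(self):
        with pytest.raises(ConfigurationError):
            Beam(power=-0.1)
        with pytest.raises(ConfigurationError):
            Beam(power=3.5, max_power=3.0)


class TestDepositEnergy:
    def test_zero_power_gives_zero_source(self, liver):
        field = ThermalField(liver)
        source = deposit_energy(field, liver, Beam(power=0.0))
        assert np.all(source == 0.0)

    def test_beer_lambert_total_absorption_closed_form(self, liver):
        # semi-infinite-slab closed form: P * (1 - exp(-mu_a * L))
        field = ThermalField(liver)
        beam = Beam(power=3.0)
        source = deposit_energy(field, liver, beam)
        expected = 3.0 * (1.0 - np.exp(-liver.mu_a_si * liver.thickness))
        got = absorbed_power(field, source)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.333, abs=5e-3)  # mu_a L = 0.585
        assert got <= beam.power

    def test_gaussian_profile_conserves_total_absorption(self, liver):
        field = ThermalField(liver)
        src = deposit_energy(field, liver, Beam(power=2.0, profile="gaussian"))
        expected = 2.0 * (1.0 - np.exp(-liver.mu_a_si * liver.thickness))
        # small tail of the gaussian falls outside the domain radius
        assert absorbed_power(field, src) == pytest.approx(expected, rel=1e-6)

    def test_doubling_mu_a_sublinear_at_surface_but_total_increases(self, liver):
        from dataclasses import replace

        beam = Beam(power=3.0)
        field = ThermalField(liver)
        double = replace(liver, mu_a=2 * liver.mu_a)
        s1 = deposit_energy(field, liver, beam)
        s2 = deposit_energy(field, double, beam)
        first_layer = lambda s: float((s[0, :] * field._cell_vol).sum())
        assert first_layer(s2) < 2.0 * first_layer(s1)
        assert absorbed_power(field, s2) > absorbed_power(field, s1)


class TestStep:
    def test_uniform_field_insulated_is_equilibrium(self, liver):
        field = ThermalField(
            liver, h=0.0, top="insulated", side="insulated", bottom="insulated"
        )
        before = field.T.copy()
        step(field, None, 1.0)
        np.testing.assert_allclose(field.T, before, rtol=0, atol=1e-12)

    def test_insulated_energy_conserved_per_step(self, liver):
        field = ThermalField(
            liver, h=0.0, top="insulated", side="insulated", bottom="insulated"
        )
        field.T += np.random.default_rng(0).normal(0, 5, field.T.shape)
        e0 = field.energy()
        step(field, None, 0.9 * field.stable_dt, substep=False)
        assert abs(field.energy() - e0) / abs(e0) < 1e-6

    def test_unstable_dt_rejected(self, liver):
        field = ThermalField(liver)
        with pytest.raises(StabilityError):
            step(field, None, 2.0 * field.stable_dt, substep=False)

    def test_energy_balance_with_source_and_losses(self, liver):
        # d/dt int(rho c T) must equal absorbed power minus boundary losses
        field = ThermalField(liver)
        source = deposit_energy(field, liver, Beam(power=3.0))
        field.advance(source, 5.0)
        e0, a0, b0 = field.energy(), field.absorbed_J, field.boundary_J
        field.advance(source, 10.0)
        lhs = field.energy() - e0
        rhs = (field.absorbed_J - a0) + (field.boundary_J - b0)
        assert lhs == pytest.approx(rhs, rel=1e-2)

    @pytest.mark.parametrize("t_check", [2.0, 5.0, 10.0])
    def test_constant_flux_analytic_oracle(self, liver, t_check):
        # 1-D semi-infinite slab under constant surface flux q:
        # T_surf(t) - T0 = (2 q / k) sqrt(alpha t / pi)
        q = 5000.0
        field = ThermalField(
            liver,
            nr=4,
            nz=130,
            radius=0.02,
            h=0.0,
            top="flux",
            side="insulated",
            bottom="dirichlet",
            top_flux=q,
        )
        field.advance(None, t_check)
        alpha, k = liver.alpha, liver.k
        surf_analytic = (2 * q / k) * np.sqrt(alpha * t_check / np.pi)
        surf_sim = field.surface_values(extrapolate=True)[0] - field.ambient
        assert surf_sim == pytest.approx(surf_analytic, rel=0.02)
        # also the full depth solution at the first cell centre
        z = field.dz / 2
        depth_analytic = (q / k) * (
            2 * np.sqrt(alpha * t_check / np.pi) * np.exp(-(z**2) / (4 * alpha * t_check))
            - z * erfc(z / (2 * np.sqrt(alpha * t_check)))
        )
        assert field.T[0, 0] - field.ambient == pytest.approx(depth_analytic, rel=0.02)

    def test_grid_convergence_under_refinement(self, liver):
        beam = Beam(power=3.0)
        axis_temp = {}
        for nr, nz in [(64, 32), (128, 64)]:
            field = ThermalField(liver, nr=nr, nz=nz)
            field.advance(deposit_energy(field, liver, beam), 60.0)
            axis_temp[nr] = surface_temperature(field).values[0]
        rise_fine = axis_temp[128] - 25.0
        assert abs(axis_temp[64] - axis_temp[128]) / rise_fine < 0.01

    def test_relaxation_monotone_toward_ambient_with_source_off(self, liver):
        field = ThermalField(liver)
        field.advance(deposit_energy(field, liver, Beam(power=3.0)), 30.0)
        peaks = [field.T.max()]
        for _ in range(10):
            field.advance(None, 5.0)
            peaks.append(field.T.max())
        assert np.all(np.diff(peaks) < 0)
        assert field.T.min() >= field.ambient - 1e-9


class TestSurfaceMap:
    def test_uniform_field_gives_uniform_map(self, liver):
        field = ThermalField(liver, initial_temp=25.0)
        surf = surface_temperature(field)
        assert np.all(surf.values == 25.0)
        assert surf.sample_xy(np.array([0.001]), np.array([0.002]))[0] == 25.0

    def test_heated_map_peaks_on_axis_and_decreases_radially(self, liver):
        field = ThermalField(liver)
        field.advance(deposit_energy(field, liver, Beam(power=3.0)), 30.0)
        vals = surface_temperature(field).values
        assert np.argmax(vals) == 0
        assert np.all(np.diff(vals) <= 1e-12)
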