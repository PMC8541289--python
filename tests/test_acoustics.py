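import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import acoustofocus as af
from acoustofocus import (
    DriveField,
    Medium,
    ParticleSpecies,
    ResonatorGeometry,
    contrast_factor,
    critical_diameter,
    design_width,
    eac_from_voltage,
    energy_density_from_displacement,
    pressure_amplitude,
    polystyrene_sphere,
    radiation_force,
    stokes_drag,
    transverse_path,
)

# water-like medium whose compressibility is pinned at the handbook value
# 4.48e-10 1/Pa (sound speed chosen consistently)
WATER_HANDBOOK = Medium(998.0, 1495.6, 1.002e-3, compressibility=4.48e-10)


class TestContrastFactor:
    def test_medium_matched_particle_is_neutral(self, water):
        sp = ParticleSpecies(1e-6, water.density, water.compressibility)
        assert contrast_factor(sp, water) == 0.0

    def test_rigid_dense_limit_approaches_five_halves(self, water):
        sp = ParticleSpecies(1e-6, 1e9, 1e-20)
        assert contrast_factor(sp, water) == pytest.approx(2.5, rel=1e-5)

    def test_polystyrene_in_water_hand_value(self):
        # (5*1050 - 2*998)/(2*1050 + 998) - 2.16/4.48, by hand: 0.5682122107
        sp = ParticleSpecies(2e-6, 1050.0, 2.16e-10)
        assert contrast_factor(sp, WATER_HANDBOOK) == pytest.approx(
            0.5682122107, abs=1e-9
        )


class TestRadiationForce:
    def test_zero_at_node(self, bead_4um, water, device_field, geometry):
        f = radiation_force(geometry.width / 2.0, bead_4um, water, device_field, geometry)
        assert f == pytest.approx(0.0, abs=1e-30)

    def test_zero_for_neutral_particle(self, water, device_field, geometry):
        neutral = ParticleSpecies(2e-6, water.density, water.compressibility)
        y = np.linspace(0.0, geometry.width, 11)
        assert np.allclose(radiation_force(y, neutral, water, device_field, geometry), 0.0)

    def test_quarter_width_value_toward_node(self, bead_4um, water, device_field, geometry):
        # independent arithmetic: F = Vp * k * Eac * phi * |sin(2k(y - w/2))|,
        # positive (toward the node) at y = w/4
        y = geometry.width / 4.0
        k = math.pi / geometry.width
        phi = contrast_factor(bead_4um, water)
        expected = bead_4um.volume * k * 7.25 * phi  # sin term = -(-1) = +1
        got = radiation_force(y, bead_4um, water, device_field, geometry)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0.0

    def test_pressure_and_energy_forms_agree(self, bead_4um, water, geometry):
        # E_ac = p0^2 beta_m / 4 makes the two prefactors identical
        field = DriveField.half_wave(geometry, water, energy_density=7.25)
        p0 = field.pressure_amplitude
        y = np.linspace(1e-6, geometry.width - 1e-6, 7)
        phi = contrast_factor(bead_4um, water)
        lam = 2.0 * geometry.width
        x = y - geometry.width / 2.0
        from_pressure = (
            -math.pi * p0**2 * bead_4um.volume * water.compressibility / (2.0 * lam)
            * phi * np.sin(4.0 * math.pi * x / lam)
        )
        got = radiation_force(y, bead_4um, water, field, geometry)
        assert np.allclose(got, from_pressure, rtol=1e-12)

    def test_outside_channel_rejected(self, bead_4um, water, device_field, geometry):
        with pytest.raises(ValueError, match="inside the channel"):
            radiation_force(-1e-6, bead_4um, water, device_field, geometry)

    def test_non_half_wave_field_rejected(self, bead_4um, water, geometry):
        detuned = DriveField(water, 4.623e6, energy_density=7.25)
        with pytest.raises(ValueError, match="half-wave"):
            radiation_force(50e-6, bead_4um, water, detuned, geometry)


class TestStokesDrag:
    def test_hand_value_and_linearity(self, water):
        sp = polystyrene_sphere(4e-6)  # a0 = 2 um
        f = stokes_drag(1e-4, sp, water)
        assert f == pytest.approx(-6.0 * math.pi * 1.002e-3 * 2e-6 * 1e-4, rel=1e-12)
        assert stokes_drag(0.0, sp, water) == 0.0
        double = polystyrene_sphere(8e-6)
        assert stokes_drag(1e-4, double, water) == pytest.approx(2.0 * f, rel=1e-12)


class TestCriticalDiameter:
    def test_inverse_square_root_in_frequency(self, water):
        d1 = critical_diameter(0.57, water, 1e6)
        d4 = critical_diameter(0.57, water, 4e6)
        assert d4 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_decreasing_in_contrast(self, water):
        assert critical_diameter(0.8, water, 4e6) < critical_diameter(0.4, water, 4e6)

    def test_negative_contrast_rejected(self, water):
        with pytest.raises(ValueError):
            critical_diameter(-0.1, water, 4e6)

    def test_device_scale_is_micrometric(self, bead_4um, water):
        phi = contrast_factor(bead_4um, water)
        d = critical_diameter(phi, water, 4.623e6)
        assert 0.5e-6 < d < 3e-6


class TestTransversePath:
    def test_no_field_keeps_position(self, bead_4um, water, geometry):
        field = DriveField.half_wave(geometry, water, energy_density=0.0)
        t = np.linspace(0.0, 100.0, 7)
        assert np.allclose(
            transverse_path(30e-6, t, bead_4um, water, field), 30e-6, rtol=1e-14
        )

    def test_node_is_fixed_point(self, bead_4um, water, device_field, geometry):
        node = geometry.width / 2.0
        y = transverse_path(node, 5.0, bead_4um, water, device_field)
        assert y == pytest.approx(node, rel=1e-14)

    def test_antinode_returns_unchanged_with_warning(
        self, bead_4um, water, device_field
    ):
        with pytest.warns(UserWarning, match="anti-node"):
            y = transverse_path(0.0, 5.0, bead_4um, water, device_field)
        assert y == 0.0

    def test_matches_overdamped_ode(self, bead_4um, water, device_field, geometry):
        eta, a0 = water.viscosity, bead_4um.radius

        def rhs(t, y):
            return [
                radiation_force(y[0], bead_4um, water, device_field, geometry)
                / (6.0 * math.pi * eta * a0)
            ]

        y0 = 0.1 * geometry.width
        ts = np.linspace(0.0, 10.0, 41)
        sol = solve_ivp(rhs, (0.0, 10.0), [y0], t_eval=ts, rtol=1e-11, atol=1e-15)
        closed = transverse_path(y0, ts, bead_4um, water, device_field)
        assert np.max(np.abs(sol.y[0] - closed) / closed) < 1e-6

    def test_round_trip_1000_random_draws(self, bead_4um, water, geometry):
        # draws whose endpoint lands within 0.1 nm of the node are redrawn:
        # the inversion's own precondition keeps endpoints off the tan
        # degeneracy (the estimator's exclusion margin enforces this on data)
        rng = np.random.default_rng(42)
        w = geometry.width
        node = w / 2.0
        worst, accepted = 0.0, 0
        while accepted < 1000:
            y0 = rng.uniform(0.01, 0.49) * w
            eac = rng.uniform(0.1, 20.0)
            t = rng.uniform(0.05, 5.0)
            field = DriveField.half_wave(geometry, water, energy_density=eac)
            yt = transverse_path(y0, t, bead_4um, water, field)
            if node - yt < 1e-10:
                continue
            back = energy_density_from_displacement(y0, yt, t, bead_4um, water, field)
            worst = max(worst, abs(back - eac) / eac)
            accepted += 1
        assert worst < 1e-9

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        y0_frac=st.floats(0.01, 0.99),
        t=st.floats(0.0, 20.0),
    )
    def test_reflection_symmetry(self, y0_frac, t):
        water, geometry = af.WATER_20C, af.ResonatorGeometry()
        bead = af.polystyrene_sphere(4e-6)
        field = af.DriveField.half_wave(geometry, water, energy_density=5.0)
        w = geometry.width
        y0 = y0_frac * w
        a = transverse_path(y0, t, bead, water, field)
        b = transverse_path(w - y0, t, bead, water, field)
        assert a == pytest.approx(w - b, abs=1e-15 * w + 1e-12 * abs(w - b))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        y0_frac=st.floats(0.02, 0.48),
        eac=st.floats(0.1, 20.0),
    )
    def test_monotone_in_time_and_energy(self, y0_frac, eac):
        water, geometry = af.WATER_20C, af.ResonatorGeometry()
        bead = af.polystyrene_sphere(4e-6)
        w = geometry.width
        field = af.DriveField.half_wave(geometry, water, energy_density=eac)
        t = np.linspace(0.0, 30.0, 40)
        path = transverse_path(y0_frac * w, t, bead, water, field)
        assert np.all(np.diff(path) >= 0.0)
        assert path[-1] <= w / 2.0 + 1e-15
        stronger = af.DriveField.half_wave(geometry, water, energy_density=2.0 * eac)
        path2 = transverse_path(y0_frac * w, t, bead, water, stronger)
        assert np.all(path2 >= path - 1e-18)


class TestEnergyFromDisplacement:
    def test_no_displacement_gives_zero(self, bead_4um, water, device_field):
        assert (
            energy_density_from_displacement(
                30e-6, 30e-6, 10.0, bead_4um, water, device_field
            )
            == 0.0
        )

    def test_halving_time_doubles_energy(self, bead_4um, water, device_field):
        e1 = energy_density_from_displacement(
            30e-6, 60e-6, 10.0, bead_4um, water, device_field
        )
        e2 = energy_density_from_displacement(
            30e-6, 60e-6, 5.0, bead_4um, water, device_field
        )
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_motion_away_from_node_rejected(self, bead_4um, water, device_field):
        with pytest.raises(ValueError, match="away from node"):
            energy_density_from_displacement(
                60e-6, 30e-6, 10.0, bead_4um, water, device_field
            )

    @pytest.mark.parametrize("y0", [0.0, 95e-6, 190e-6])
    def test_degenerate_positions_rejected(self, y0, bead_4um, water, device_field):
        with pytest.raises(ValueError):
            energy_density_from_displacement(
                y0, 50e-6, 10.0, bead_4um, water, device_field
            )


class TestPressureAmplitude:
    def test_zero_energy_zero_pressure(self, water):
        assert pressure_amplitude(0.0, water) == 0.0

    def test_square_root_scaling(self, water):
        assert pressure_amplitude(4.0, water) == pytest.approx(
            2.0 * pressure_amplitude(1.0, water), rel=1e-12
        )

    def test_reference_energy_density_gives_quarter_mpa(self, water):
        # 2 * 1481 * sqrt(7.25 * 998) = 0.252 MPa to the printed precision
        assert pressure_amplitude(7.25, water) / 1e6 == pytest.approx(0.252, abs=5e-4)

    def test_inverse(self, water):
        pa = pressure_amplitude(3.3, water)
        assert af.energy_density_from_pressure(pa, water) == pytest.approx(3.3, rel=1e-12)


class TestDesignWidth:
    def test_hand_value(self):
        m = Medium(998.0, 1497.0, 1e-3)
        assert design_width(m, 4.0e6) == pytest.approx(187.125e-6, rel=1e-12)

    def test_doubling_frequency_halves_width(self, water):
        assert design_width(water, 8e6) == pytest.approx(
            design_width(water, 4e6) / 2.0, rel=1e-12
        )

    def test_inverse_identity(self, water):
        w = design_width(water, 3.897e6)
        assert water.sound_speed / (2.0 * w) == pytest.approx(3.897e6, rel=1e-12)


class TestVoltageCalibration:
    def test_zero_voltage(self):
        assert eac_from_voltage(0.0) == 0.0

    def test_measurement_condition_anchor(self):
        assert eac_from_voltage(52.92) == pytest.approx(7.25, rel=1e-12)

    def test_quadratic_scaling(self):
        assert eac_from_voltage(26.46) == pytest.approx(7.25 / 4.0, rel=1e-12)


class TestDriveField:
    def test_half_wave_matches_geometry(self, geometry, water):
        field = DriveField.half_wave(geometry, water, energy_density=1.0)
        assert field.wavelength == pytest.approx(2.0 * geometry.width, rel=1e-12)
        assert field.wavenumber * field.wavelength == pytest.approx(
            2.0 * math.pi, rel=1e-12
        )

    def test_energy_and_pressure_cross_derived(self, geometry, water):
        f1 = DriveField.half_wave(geometry, water, energy_density=7.25)
        f2 = DriveField(
            water, f1.frequency, pressure_amplitude=f1.pressure_amplitude
        )
        assert f2.energy_density == pytest.approx(7.25, rel=1e-9)

    def test_inconsistent_pair_rejected(self, water):
        with pytest.raises(ValueError, match="inconsistent"):
            DriveField(water, 4e6, energy_density=7.25, pressure_amplitude=1e5)

    def test_voltage_constructor(self, geometry, water):
        field = DriveField.half_wave(geometry, water, vpp=52.92)
        assert field.energy_density == pytest.approx(7.25, rel=1e-12)
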