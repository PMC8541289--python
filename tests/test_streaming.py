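import numpy as np
import pytest

import acoustofocus as af
from acoustofocus.streaming import (
    FirstOrderField,
    StreamingSolution,
    first_order_field,
    limiting_velocity,
    rayleigh_slip_amplitude,
    solve_streaming,
    streaming_velocity_at,
)


class TestFirstOrderField:
    def test_antinode_at_walls_node_at_centre(self, operating_field, geometry):
        f1 = first_order_field(operating_field, geometry, (65, 32))
        pa = operating_field.pressure_amplitude
        assert abs(f1.pressure[0]) == pytest.approx(pa, rel=1e-12)
        assert abs(f1.pressure[-1]) == pytest.approx(pa, rel=1e-12)
        mid = len(f1.y) // 2
        assert abs(f1.pressure[mid]) < 1e-9 * pa
        # velocity is maximal at the node
        assert np.argmax(np.abs(f1.v1)) == mid

    def test_helmholtz_residual_second_order_convergence(
        self, operating_field, geometry
    ):
        scale = (
            operating_field.angular_frequency / operating_field.medium.sound_speed
        ) ** 2 * operating_field.pressure_amplitude
        residuals = []
        for ny in (32, 64, 128):
            f1 = first_order_field(operating_field, geometry, (ny, 16))
            residuals.append(np.max(np.abs(f1.helmholtz_residual())) / scale)
        # halving h divides the residual by ~4
        assert residuals[0] / residuals[1] == pytest.approx(4.0, rel=0.15)
        assert residuals[1] / residuals[2] == pytest.approx(4.0, rel=0.15)

    def test_detuned_field_rejected(self, geometry, water):
        detuned = af.DriveField(water, 4.623e6, energy_density=7.25)
        with pytest.raises(ValueError, match="half-wave"):
            first_order_field(detuned, geometry, (64, 32))

    def test_too_coarse_grid_rejected(self, operating_field, geometry):
        with pytest.raises(ValueError, match="at least"):
            first_order_field(operating_field, geometry, (16, 8))


class TestLimitingVelocity:
    def test_zero_field_gives_zero_slip(self, operating_field, geometry):
        f1 = first_order_field(operating_field, geometry, (64, 32))
        quiet = FirstOrderField(
            y=f1.y, z=f1.z,
            pressure=np.zeros_like(f1.pressure),
            v1=np.zeros_like(f1.v1),
            omega=f1.omega, sound_speed=f1.sound_speed, density=f1.density,
        )
        lv = limiting_velocity(quiet)
        assert np.all(lv.bottom == 0.0)
        assert np.all(lv.top == 0.0)

    def test_matches_classical_rayleigh_slip(self, operating_field, geometry):
        # vL = -(3/8)(U^2/c) sin(2ky) for v1 = iU sin(ky)
        f1 = first_order_field(operating_field, geometry, (128, 32))
        lv = limiting_velocity(f1)
        med = operating_field.medium
        u_amp = operating_field.pressure_amplitude / (med.density * med.sound_speed)
        expected = -3.0 / 8.0 * u_amp**2 / med.sound_speed * np.sin(
            2.0 * f1.wavenumber * f1.y
        )
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(lv.bottom - expected)) < 0.01 * scale
        assert rayleigh_slip_amplitude(operating_field) == pytest.approx(
            3.0 / 8.0 * u_amp**2 / med.sound_speed, rel=1e-12
        )

    def test_slip_vanishes_at_walls_and_node(self, operating_field, geometry):
        f1 = first_order_field(operating_field, geometry, (129, 32))
        lv = limiting_velocity(f1)
        scale = np.max(np.abs(lv.bottom))
        mid = len(f1.y) // 2
        assert abs(lv.bottom[0]) < 1e-3 * scale
        assert abs(lv.bottom[-1]) < 1e-3 * scale
        assert abs(lv.bottom[mid]) < 1e-3 * scale
        # side walls carry no slip for the pure transverse mode
        assert np.all(lv.left == 0.0)
        assert np.all(lv.right == 0.0)


class TestStokesSolve:
    def test_zero_slip_gives_zero_flow(self, operating_field, geometry, water):
        f1 = first_order_field(operating_field, geometry, (48, 24))
        quiet = FirstOrderField(
            y=f1.y, z=f1.z,
            pressure=np.zeros_like(f1.pressure),
            v1=np.zeros_like(f1.v1),
            omega=f1.omega, sound_speed=f1.sound_speed, density=f1.density,
        )
        sol = solve_streaming(limiting_velocity(quiet), geometry, water)
        assert np.max(np.abs(sol.v2y)) == 0.0
        assert np.max(np.abs(sol.v2z)) == 0.0

    def test_divergence_free(self, streaming_solution):
        vmax = np.max(np.hypot(streaming_solution.v2y, streaming_solution.v2z))
        h = streaming_solution.y[1] - streaming_solution.y[0]
        assert streaming_solution.max_divergence() < 1e-10 * vmax / h

    def test_four_roll_sign_pattern(self, streaming_solution):
        # vertical velocity at mid-height changes sign across y = w/4 and 3w/4
        sol = streaming_solution
        ny = len(sol.y)
        iz = len(sol.z) // 2
        v2z_mid = sol.v2z[:, iz]
        s1 = np.sign(v2z_mid[int(0.125 * ny)])
        s2 = np.sign(v2z_mid[int(0.375 * ny)])
        s3 = np.sign(v2z_mid[int(0.625 * ny)])
        s4 = np.sign(v2z_mid[int(0.875 * ny)])
        assert s1 == -s2
        assert s3 == -s4
        assert s2 == s3  # mirror pair about the node

    def test_antisymmetric_under_reflection(self, streaming_solution):
        psi = streaming_solution.psi
        assert np.max(np.abs(psi + psi[::-1, :])) < 1e-3 * np.max(np.abs(psi))

    def test_wall_velocity_matches_slip(self, operating_field, geometry, water):
        f1 = first_order_field(operating_field, geometry, (128, 64))
        lv = limiting_velocity(f1)
        sol = solve_streaming(lv, geometry, water)
        scale = np.max(np.abs(lv.bottom))
        assert np.max(np.abs(sol.v2y[:, 0] - lv.bottom)) < 0.05 * scale
        assert np.max(np.abs(sol.v2y[:, -1] - lv.top)) < 0.05 * scale

    def test_roll_velocity_grid_convergence(self, operating_field, geometry, water):
        # peak mid-height vertical roll velocity converges at ~2nd order
        values = []
        for shape in ((32, 16), (64, 32), (128, 64)):
            f1 = first_order_field(operating_field, geometry, shape)
            sol = solve_streaming(limiting_velocity(f1), geometry, water)
            values.append(np.max(np.abs(sol.v2z[:, len(sol.z) // 2])))
        err_coarse = abs(values[0] - values[2])
        err_mid = abs(values[1] - values[2])
        order = np.log2(err_coarse / err_mid) if err_mid > 0 else 2.0
        assert order > 1.5

    def test_streaming_slow_against_supercritical_beads(
        self, streaming_solution, operating_field, bead_4um, bead_500nm, water
    ):
        # velocity-scale ordering at the operating point: streaming sits
        # between the acoustophoretic speeds of sub- and super-critical sizes
        slip = rayleigh_slip_amplitude(operating_field)
        k = operating_field.wavenumber
        u4 = af.mobility_rate(bead_4um, water, operating_field) / (2.0 * k)
        u_np = af.mobility_rate(bead_500nm, water, operating_field) / (2.0 * k)
        assert u_np < slip < u4


class TestInterpolation:
    def test_grid_node_query_exact(self, streaming_solution):
        sol = streaming_solution
        i, j = 10, 7
        v = streaming_velocity_at((sol.y[i], sol.z[j]), sol)
        assert v[0] == pytest.approx(sol.v2y[i, j], rel=1e-12, abs=1e-30)
        assert v[1] == pytest.approx(sol.v2z[i, j], rel=1e-12, abs=1e-30)

    def test_outside_domain_rejected(self, streaming_solution):
        with pytest.raises(ValueError):
            streaming_velocity_at((-1e-6, 1e-6), streaming_solution)

    def test_mid_cell_equals_average_on_linear_field(self, geometry, water):
        y = np.linspace(0.0, geometry.width, 16)
        z = np.linspace(0.0, geometry.height, 8)
        yy, zz = np.meshgrid(y, z, indexing="ij")
        linear = 3.0 * yy + 2.0 * zz
        sol = StreamingSolution(
            y=y, z=z, psi=np.zeros_like(linear),
            v2y=linear, v2z=2.0 * linear,
            p2=np.zeros_like(linear), viscosity=water.viscosity,
        )
        ym = 0.5 * (y[3] + y[4])
        zm = 0.5 * (z[2] + z[3])
        v = streaming_velocity_at((ym, zm), sol)
        expected = 3.0 * ym + 2.0 * zm
        assert v[0] == pytest.approx(expected, rel=1e-12)
        assert v[1] == pytest.approx(2.0 * expected, rel=1e-12)
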