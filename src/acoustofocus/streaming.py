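"""Boundary-driven (Rayleigh) acoustic streaming in the channel cross-section.

The model follows the limiting-velocity method: the first-order acoustic
field is evaluated analytically for the ideal half-wave transverse mode
(pressure anti-nodes at the side walls, node at the channel centre), an
effective tangential slip velocity is computed on the walls from the
first-order field, and the second-order time-averaged flow is obtained by
solving incompressible Stokes flow in the rectangular cross-section with
that slip as the tangential wall boundary condition.  The viscous boundary
layer itself is never resolved; its net effect is condensed into the slip.

For a pure transverse standing wave ``v1 = i U sin(k y)`` the slip reduces
to the classical Rayleigh value ``-(3/8)(U^2/c) sin(2 k y)`` on the top and
bottom walls, directed from the pressure node toward the anti-nodes, which
drives the textbook four-roll pattern in the cross-section.

The Stokes solve uses a streamfunction--vorticity formulation: with
``v2y = dpsi/dz`` and ``v2z = -dpsi/dy`` continuity is identity and the
momentum equation reduces to the biharmonic problem ``lap(omega) = 0``,
``omega = -lap(psi)``.  Both fields are assembled into one sparse linear
system (Thom-type wall-vorticity closure carrying the slip) and solved
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve

from .acoustics import DriveField, ResonatorGeometry
from .materials import Medium

__all__ = [
    "FirstOrderField",
    "LimitingVelocityField",
    "StreamingSolution",
    "first_order_field",
    "limiting_velocity",
    "solve_streaming",
    "streaming_velocity_at",
    "rayleigh_slip_amplitude",
]


@dataclass(frozen=True)
class FirstOrderField:
    """First-order (acoustic) field sampled on a (y, z) cross-section grid.

    ``pressure`` and ``v1`` are complex amplitudes of the harmonic field; the
    axial and vertical first-order velocities vanish for the pure transverse
    standing wave (``u1 = w1 = 0``).
    """

    y: np.ndarray  # (ny,) transverse positions, m
    z: np.ndarray  # (nz,) vertical positions, m
    pressure: np.ndarray  # (ny,) complex Pa
    v1: np.ndarray  # (ny,) complex m/s, transverse component
    omega: float  # rad/s
    sound_speed: float  # m/s
    density: float  # kg/m^3

    @property
    def wavenumber(self) -> float:
        return math.pi / self.y[-1]

    def helmholtz_residual(self) -> np.ndarray:
        """Discrete residual of ``lap p + (omega/c)^2 p`` at interior nodes."""
        h = self.y[1] - self.y[0]
        lap = (self.pressure[2:] - 2.0 * self.pressure[1:-1] + self.pressure[:-2]) / h**2
        return lap + (self.omega / self.sound_speed) ** 2 * self.pressure[1:-1]


@dataclass(frozen=True)
class LimitingVelocityField:
    """Wall-tangential limiting (slip) velocities along each wall.

    ``bottom``/``top`` hold the y-directed slip sampled along y on the walls
    ``z = 0`` and ``z = h_ch``; ``left``/``right`` hold the z-directed slip
    along z on the side walls (identically zero for the analytic transverse
    mode).  ``qy`` is the convective intermediate product on the top/bottom
    walls.
    """

    y: np.ndarray
    z: np.ndarray
    bottom: np.ndarray
    top: np.ndarray
    left: np.ndarray
    right: np.ndarray
    qy: np.ndarray


@dataclass(frozen=True)
class StreamingSolution:
    """Second-order time-averaged streaming flow in the cross-section."""

    y: np.ndarray  # (ny,)
    z: np.ndarray  # (nz,)
    psi: np.ndarray  # (ny, nz) streamfunction, m^2/s
    v2y: np.ndarray  # (ny, nz) m/s
    v2z: np.ndarray  # (ny, nz) m/s
    p2: np.ndarray  # (ny, nz) Pa
    viscosity: float

    def max_divergence(self) -> float:
        """Max |div v2| at interior nodes (central differences)."""
        dy = self.y[1] - self.y[0]
        dz = self.z[1] - self.z[0]
        div = (
            (self.v2y[2:, 1:-1] - self.v2y[:-2, 1:-1]) / (2.0 * dy)
            + (self.v2z[1:-1, 2:] - self.v2z[1:-1, :-2]) / (2.0 * dz)
        )
        return float(np.max(np.abs(div)))

    def interpolator(self) -> RegularGridInterpolator:
        values = np.stack([self.v2y, self.v2z], axis=-1)
        return RegularGridInterpolator((self.y, self.z), values, method="linear")

    def to_dataframe(self):
        import pandas as pd

        yy, zz = np.meshgrid(self.y, self.z, indexing="ij")
        return pd.DataFrame(
            {
                "y_m": yy.ravel(),
                "z_m": zz.ravel(),
                "v2y_m_s": self.v2y.ravel(),
                "v2z_m_s": self.v2z.ravel(),
                "p2_pa": self.p2.ravel(),
            }
        )

    def quiver_plot(self, path, stride: int = 4) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        s = slice(None, None, stride)
        ax.quiver(
            self.y[s] * 1e6,
            self.z[s] * 1e6,
            self.v2y[s, s].T,
            self.v2z[s, s].T,
            np.hypot(self.v2y[s, s], self.v2z[s, s]).T,
        )
        ax.set_xlabel("y (um)")
        ax.set_ylabel("z (um)")
        ax.set_title("second-order streaming velocity")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def rayleigh_slip_amplitude(field: DriveField) -> float:
    """Classical Rayleigh slip amplitude ``(3/8) U^2/c`` (m/s), U = p_a/(rho c)."""
    u = field.pressure_amplitude / (field.medium.density * field.medium.sound_speed)
    return 3.0 / 8.0 * u**2 / field.medium.sound_speed


def first_order_field(
    field: DriveField,
    geometry: ResonatorGeometry,
    grid_shape: tuple[int, int] = (128, 64),
) -> FirstOrderField:
    """Analytic half-wave standing wave sampled on a (y, z) grid.

    ``p(y) = p_a cos(k y)`` (anti-nodes at the walls, node at the centre)
    and ``v1(y) = i (p_a/(rho c)) sin(k y)``; ``u1 = w1 = 0``.
    """
    ny, nz = grid_shape
    if ny < 32 or nz < 16:
        raise ValueError("grid must be at least 32 x 16")
    if not field.matches_half_wave(geometry, rtol=1e-9):
        raise ValueError(
            "first_order_field requires the half-wave mode lambda = 2 w_ch "
            f"(field wavelength {field.wavelength:g} m, channel width {geometry.width:g} m)"
        )
    pa = field.pressure_amplitude
    rho, c = field.medium.density, field.medium.sound_speed
    y = np.linspace(0.0, geometry.width, ny)
    z = np.linspace(0.0, geometry.height, nz)
    k = field.wavenumber
    pressure = pa * np.cos(k * y) + 0.0j
    v1 = 1j * (pa / (rho * c)) * np.sin(k * y)
    return FirstOrderField(
        y=y, z=z, pressure=pressure, v1=v1,
        omega=field.angular_frequency, sound_speed=c, density=rho,
    )


def limiting_velocity(f1: FirstOrderField) -> LimitingVelocityField:
    """Wall slip velocities from the first-order field.

    Each limiting-velocity component pairs the first-order velocity with its
    own complex conjugate:

        vL = -(1/(4 omega)) Re{ q_y + v1* [ (2 + i) div(v1) ] },
        q_y = u1 d(v1*)/dx + v1 d(v1*)/dy,

    evaluated on the top and bottom walls (the boundary-normal terms drop
    there).  For the analytic y-only mode ``u1 = w1 = 0`` so ``q_x`` and the
    side-wall slip vanish identically; derivatives are taken with
    second-order finite differences so the formula applies to any sampled
    first-order field.
    """
    v1 = f1.v1
    dv1_dy = np.gradient(v1, f1.y, edge_order=2)
    qy = v1 * np.conj(dv1_dy)
    div_v1 = dv1_dy  # u1 = w1 = 0 for the transverse mode
    slip = -(1.0 / (4.0 * f1.omega)) * np.real(
        qy + np.conj(v1) * (2.0 + 1.0j) * div_v1
    )
    zeros_z = np.zeros_like(f1.z)
    return LimitingVelocityField(
        y=f1.y, z=f1.z, bottom=slip, top=slip.copy(),
        left=zeros_z, right=zeros_z.copy(), qy=qy,
    )


def solve_streaming(
    lv: LimitingVelocityField,
    geometry: ResonatorGeometry,
    medium: Medium,
    divergence_tol: float = 1e-10,
) -> StreamingSolution:
    """Stokes flow in the cross-section driven by wall slip.

    Solves ``grad p2 = mu lap v2``, ``div v2 = 0`` on the rectangle
    ``[0, w_ch] x [0, h_ch]`` with no-penetration everywhere and tangential
    velocity equal to the limiting velocity on each wall, via the coupled
    sparse (psi, omega) system.  The returned velocity field is exactly
    divergence-free in the discrete (central-difference) sense.
    """
    y, z = lv.y, lv.z
    ny, nz = y.size, z.size
    hy, hz = y[1] - y[0], z[1] - z[0]
    n = ny * nz

    def idx(i, j):
        return i * nz + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(2 * n)
    eq = 0

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # unknown ordering: psi at [0, n), omega at [n, 2n)
    for i in range(ny):
        for j in range(nz):
            p = idx(i, j)
            boundary = i == 0 or i == ny - 1 or j == 0 or j == nz - 1
            if not boundary:
                # lap psi + omega = 0
                r = 2 * p
                add(r, p, -2.0 / hy**2 - 2.0 / hz**2)
                add(r, idx(i - 1, j), 1.0 / hy**2)
                add(r, idx(i + 1, j), 1.0 / hy**2)
                add(r, idx(i, j - 1), 1.0 / hz**2)
                add(r, idx(i, j + 1), 1.0 / hz**2)
                add(r, n + p, 1.0)
                # lap omega = 0
                r = 2 * p + 1
                add(r, n + p, -2.0 / hy**2 - 2.0 / hz**2)
                add(r, n + idx(i - 1, j), 1.0 / hy**2)
                add(r, n + idx(i + 1, j), 1.0 / hy**2)
                add(r, n + idx(i, j - 1), 1.0 / hz**2)
                add(r, n + idx(i, j + 1), 1.0 / hz**2)
                continue
            # boundary: psi = 0
            add(2 * p, p, 1.0)
            # boundary: Thom wall-vorticity closure with slip.
            # bottom wall z=0, tangential v_y = dpsi/dz = s:
            #   omega_w = 2 (hz s - psi_adj) / hz^2
            r = 2 * p + 1
            corner = (i == 0 or i == ny - 1) and (j == 0 or j == nz - 1)
            if corner:
                # slip vanishes at corners; use the side-wall closure
                add(r, n + p, 1.0)
                add(r, idx(1 if i == 0 else ny - 2, j), 2.0 / hy**2)
            elif j == 0:
                add(r, n + p, 1.0)
                add(r, idx(i, 1), 2.0 / hz**2)
                rhs[r] = 2.0 * lv.bottom[i] / hz
            elif j == nz - 1:
                add(r, n + p, 1.0)
                add(r, idx(i, nz - 2), 2.0 / hz**2)
                rhs[r] = -2.0 * lv.top[i] / hz
            elif i == 0:
                # left wall y=0, tangential v_z = -dpsi/dy = s
                add(r, n + p, 1.0)
                add(r, idx(1, j), 2.0 / hy**2)
                rhs[r] = -2.0 * lv.left[j] / hy
            else:
                add(r, n + p, 1.0)
                add(r, idx(ny - 2, j), 2.0 / hy**2)
                rhs[r] = 2.0 * lv.right[j] / hy

    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(2 * n, 2 * n)
    )
    sol = spsolve(mat, rhs)
    psi = sol[:n].reshape(ny, nz)
    omega = sol[n:].reshape(ny, nz)

    v2y = np.gradient(psi, z, axis=1, edge_order=2)
    v2z = -np.gradient(psi, y, axis=0, edge_order=2)

    # second-order pressure from the vorticity of the Stokes balance:
    # dp/dy = -mu domega/dz, dp/dz = mu domega/dy (curl-free since lap omega = 0)
    mu = medium.viscosity
    gy = -mu * np.gradient(omega, z, axis=1, edge_order=2)
    gz = mu * np.gradient(omega, y, axis=0, edge_order=2)
    p2 = np.zeros((ny, nz))
    p2[:, 0] = cumulative_trapezoid(gy[:, 0], y, initial=0.0)
    p2 += cumulative_trapezoid(gz, z, axis=1, initial=0.0)

    solution = StreamingSolution(
        y=y, z=z, psi=psi, v2y=v2y, v2z=v2z, p2=p2, viscosity=mu
    )
    vmax = float(np.max(np.abs([solution.v2y, solution.v2z])))
    if vmax > 0.0:
        k = math.pi / geometry.width
        if solution.max_divergence() > divergence_tol * vmax * k * max(
            1.0, 4.0 / (min(hy, hz) * k)
        ):
            raise RuntimeError("streaming solution failed the divergence check")
    return solution


def streaming_velocity_at(points, sol: StreamingSolution) -> np.ndarray:
    """Bilinear interpolation of (v2y, v2z) at ``points`` (..., 2) = (y, z).

    Exact at grid nodes; raises for points outside the cross-section.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    out = sol.interpolator()(pts)
    return out[0] if single else out
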