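"""Laminar axial transport: pressure-driven flow in a rectangular duct.

The carrier flow down the separation channel is the classical Fourier-series
solution for fully developed laminar flow in a rectangular cross-section,
rescaled so that the numerically integrated flux equals the requested
volumetric flow rate (so the normalisation is exact regardless of the series
truncation).
"""

from __future__ import annotations

import numpy as np

from .acoustics import ResonatorGeometry

__all__ = ["DuctFlow", "ul_min_to_m3_s"]


def ul_min_to_m3_s(flow_rate_ul_min: float) -> float:
    """Convert a flow rate from uL/min to m^3/s."""
    return flow_rate_ul_min * 1e-9 / 60.0


class DuctFlow:
    """Axial Poiseuille profile ``u(y, z)`` in a rectangular duct.

    Parameters
    ----------
    geometry : ResonatorGeometry
        Channel cross-section (width along y, height along z).
    flow_rate : float
        Volumetric flow rate in m^3/s (use :func:`ul_min_to_m3_s`).
    n_terms : int
        Number of odd Fourier terms kept (default 11).
    """

    def __init__(
        self,
        geometry: ResonatorGeometry,
        flow_rate: float,
        n_terms: int = 11,
    ) -> None:
        if flow_rate < 0.0:
            raise ValueError("flow_rate must be non-negative")
        self.geometry = geometry
        self.flow_rate = flow_rate
        self._modes = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd i
        self._signs = (-1.0) ** ((self._modes - 1) / 2)
        # numeric normalisation: integral of the profile over the section = Q
        yq = np.linspace(0.0, geometry.width, 201)
        zq = np.linspace(0.0, geometry.height, 101)
        shape = self._shape(yq[:, None], zq[None, :])
        integral = np.trapezoid(np.trapezoid(shape, zq, axis=1), yq, axis=0)
        self._scale = flow_rate / integral if integral > 0.0 else 0.0

    def _shape(self, y, z):
        """Unnormalised profile; exact no-slip at all four walls."""
        w, h = self.geometry.width, self.geometry.height
        yc = np.asarray(y) - w / 2.0
        zc = np.asarray(z) - h / 2.0
        i = self._modes
        arg = np.pi / w
        # expansion along the wide (y) direction, hyperbolic decay in z
        terms = (
            self._signs
            / i**3
            * np.cos(i * arg * yc[..., None])
            * (
                1.0
                - np.cosh(i * arg * zc[..., None])
                / np.cosh(i * arg * (h / 2.0))
            )
        )
        return terms.sum(axis=-1)

    def velocity(self, y, z):
        """Axial velocity (m/s) at (y, z); zero at walls, error outside."""
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        if np.any(y < 0.0) or np.any(y > self.geometry.width) or np.any(
            z < 0.0
        ) or np.any(z > self.geometry.height):
            raise ValueError("(y, z) must lie inside the channel cross-section")
        out = self._scale * self._shape(y, z)
        out = np.asarray(out)
        return float(out) if out.ndim == 0 else out

    @property
    def mean_velocity(self) -> float:
        """Cross-section-averaged velocity ``Q/(w_ch h_ch)`` (m/s)."""
        return self.flow_rate / (self.geometry.width * self.geometry.height)
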