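"""Material properties of the suspending fluid and of particle species.

The acoustofluidic closed forms need four fluid parameters (density,
compressibility, dynamic viscosity, sound speed) and three particle
parameters (radius, density, compressibility).  Compressibility and sound
speed of a fluid are not independent: for a lossless fluid
``beta = 1/(rho * c**2)``, and :class:`Medium` derives one from the other
when only one is supplied, or validates mutual consistency to 1% when both
are given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")


@dataclass(frozen=True)
class Medium:
    """A Newtonian suspending fluid.

    Parameters
    ----------
    density : float
        Mass density ``rho_m`` in kg/m^3.
    sound_speed : float
        Speed of sound ``c_m`` in m/s.
    viscosity : float
        Dynamic viscosity ``eta_m`` in Pa s.
    compressibility : float, optional
        Isentropic compressibility ``beta_m`` in 1/Pa.  Derived as
        ``1/(rho_m c_m**2)`` when omitted; when given it must agree with
        that relation to 1%.
    name : str
        Free-text label.
    """

    density: float
    sound_speed: float
    viscosity: float
    compressibility: float | None = None
    name: str = "medium"

    def __post_init__(self) -> None:
        _require_positive("density", self.density)
        _require_positive("sound_speed", self.sound_speed)
        _require_positive("viscosity", self.viscosity)
        derived = 1.0 / (self.density * self.sound_speed**2)
        if self.compressibility is None:
            object.__setattr__(self, "compressibility", derived)
        else:
            _require_positive("compressibility", self.compressibility)
            if abs(self.compressibility - derived) > 0.01 * derived:
                raise ValueError(
                    "compressibility and sound_speed are inconsistent: "
                    f"got beta={self.compressibility:.4g} 1/Pa but "
                    f"1/(rho c^2)={derived:.4g} 1/Pa (must agree within 1%)"
                )


@dataclass(frozen=True)
class ParticleSpecies:
    """A monodisperse spherical particle (bead or cell) population.

    Parameters
    ----------
    radius : float
        Particle radius ``a0`` in m.
    density : float
        Particle density ``rho_p`` in kg/m^3.
    compressibility : float
        Particle compressibility ``beta_p`` in 1/Pa.
    label : str
        Free-text label (e.g. ``"4MP"``).
    """

    radius: float
    density: float
    compressibility: float
    label: str = "particle"

    def __post_init__(self) -> None:
        _require_positive("radius", self.radius)
        _require_positive("density", self.density)
        _require_positive("compressibility", self.compressibility)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def volume(self) -> float:
        """Sphere volume ``V_p = (4/3) pi a0^3`` in m^3."""
        return 4.0 / 3.0 * math.pi * self.radius**3


#: Water at 20 degC.  These constants reproduce the device-scale pressure
#: amplitude benchmark (7.25 J/m^3 -> 0.252 MPa).
WATER_20C = Medium(
    density=998.0, sound_speed=1481.0, viscosity=1.002e-3, name="water (20 degC)"
)

#: Bulk polystyrene properties used for the fluorescent tracer beads.
POLYSTYRENE_DENSITY = 1050.0  # kg/m^3
POLYSTYRENE_COMPRESSIBILITY = 2.16e-10  # 1/Pa


def polystyrene_sphere(diameter: float, label: str | None = None) -> ParticleSpecies:
    """Polystyrene bead of the given diameter (m)."""
    if label is None:
        label = f"PS {diameter * 1e6:g} um"
    return ParticleSpecies(
        radius=diameter / 2.0,
        density=POLYSTYRENE_DENSITY,
        compressibility=POLYSTYRENE_COMPRESSIBILITY,
        label=label,
    )
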