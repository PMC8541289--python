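"""Acoustic energy density from tracked transverse particle paths.

A particle released at ``y0`` relaxes toward the pressure node along the
closed-form transverse path, so ``ln tan(k y(t))`` is linear in time with
slope ``(4 phi / 9 eta_m)(k r)^2 E_ac``.  Each tracked path therefore
yields one energy-density estimate.  Three per-path methods are provided:

``"path"`` (default)
    Nonlinear least squares of the closed-form path against the observed
    positions.  Localisation noise is additive in position, so this fit is
    unbiased even when the path saturates at the node within a few frames;
    it uses every frame and needs no sample exclusion.
``"regression"``
    Least-squares slope of ``ln tan(k y)`` vs ``t`` over the pre-arrival
    window, excluding samples too close to the node or a wall (tan
    degeneracy).  Simple and transparent, but the node-side exclusion
    selects against upward noise excursions and leaves a small negative
    bias when only a few frames precede node arrival.
``"endpoints"``
    The literal two-point displacement inversion.

Per-path estimates over an ensemble of tracked particles are summarised as
mean +/- sample standard deviation, with the corresponding in-channel
pressure amplitude attached.

Tracks are ingested from the CSV exports of video-tracking software
(columns ``particle_id, t, y``), with declared time/length units including
pixel coordinates at a stated pixel size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import (
    DriveField,
    ResonatorGeometry,
    contrast_factor,
    energy_density_from_displacement,
    pressure_amplitude,
)
from .materials import Medium, ParticleSpecies

__all__ = [
    "Trajectory",
    "EnergyDensityEstimate",
    "EstimationError",
    "load_trajectories",
    "estimate_per_particle",
    "estimate_energy_density",
]

logger = logging.getLogger(__name__)

_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_LENGTH_UNITS = {"m": 1.0, "um": 1e-6, "px": None}

#: Samples closer than this to the node or a wall are excluded from the
#: fit: tan(k y) degenerates there and localisation noise is amplified.
#: Default is two pixels at the 4x-objective scale.
DEFAULT_EXCLUDE_MARGIN = 2.0 * 1.63e-6


class EstimationError(ValueError):
    """Raised when an energy-density estimate cannot be formed."""


@dataclass
class Trajectory:
    """One particle's time-stamped transverse positions (SI units)."""

    particle_id: str
    t: np.ndarray  # s, strictly increasing
    y: np.ndarray  # m, within [0, w_ch]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError(f"particle {self.particle_id}: times not strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class EnergyDensityEstimate:
    """Ensemble energy-density estimate with uncertainty."""

    mean: float  # J/m^3
    std: float  # J/m^3, sample std across particles
    per_particle: dict[str, float]
    n: int
    pressure_amplitude: float  # Pa, from the mean via the square-root law
    rejected: dict[str, str] = dataclass_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_j_m3": self.mean,
            "std_j_m3": self.std,
            "n_particles": self.n,
            "pressure_amplitude_pa": self.pressure_amplitude,
            "per_particle_j_m3": self.per_particle,
            "rejected": self.rejected,
        }


def load_trajectories(
    path: str | Path,
    time_unit: str = "s",
    length_unit: str = "m",
    pixel_size: float | None = None,
) -> list[Trajectory]:
    """Read tracking-software CSV exports into unit-normalised trajectories.

    Expects columns ``particle_id``, ``t`` and ``y``; ``time_unit`` is
    ``"s"`` or ``"ms"``, ``length_unit`` is ``"m"``, ``"um"`` or ``"px"``
    (the latter requires ``pixel_size`` in m/pixel).  Rows with missing
    values are dropped (logged); particles with non-monotone time stamps or
    fewer than 3 samples are rejected per particle (logged), the rest load.
    """
    if time_unit not in _TIME_UNITS:
        raise ValueError(f"unknown time unit {time_unit!r}")
    if length_unit not in _LENGTH_UNITS:
        raise ValueError(f"unknown length unit {length_unit!r}")
    if length_unit == "px":
        if pixel_size is None or pixel_size <= 0.0:
            raise ValueError("pixel-space data needs a positive pixel_size (m/pixel)")
        length_scale = pixel_size
    else:
        length_scale = _LENGTH_UNITS[length_unit]

    df = pd.read_csv(path)
    missing = {"particle_id", "t", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks columns: {sorted(missing)}")
    n_before = len(df)
    df = df.dropna(subset=["t", "y"])
    if len(df) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(df))

    out: list[Trajectory] = []
    n_rejected = 0
    for pid, group in df.groupby("particle_id", sort=False):
        t = group["t"].to_numpy(dtype=float) * _TIME_UNITS[time_unit]
        y = group["y"].to_numpy(dtype=float) * length_scale
        try:
            traj = Trajectory(particle_id=str(pid), t=t, y=y)
        except ValueError as exc:
            logger.warning("rejected particle %s: %s", pid, exc)
            n_rejected += 1
            continue
        if len(traj) < 3:
            logger.warning("rejected particle %s: fewer than 3 samples", pid)
            n_rejected += 1
            continue
        out.append(traj)
    if n_rejected:
        logger.info("rejected %d particle(s) during loading", n_rejected)
    return out


def _fit_window(
    traj: Trajectory,
    k: float,
    node: float,
    width: float,
    exclude_margin: float,
):
    """Fold the track onto the lower half-channel and select the fit window.

    The window runs from the first sample to the first arrival within
    ``exclude_margin`` of the node; samples within the margin of a wall or
    the node are excluded (tan degeneracy).
    """
    y = traj.y
    lower = y[0] <= node
    yf = y if lower else width - y
    arrived = np.flatnonzero(yf >= node - exclude_margin)
    end = arrived[0] if arrived.size else yf.size
    yf = yf[:end]
    t = traj.t[:end]
    keep = (yf > exclude_margin) & (yf < node - exclude_margin)
    return t[keep], yf[keep]


def _rate_to_eac(
    rate: float, species: ParticleSpecies, medium: Medium, k: float
) -> float:
    phi = contrast_factor(species, medium)
    return float(
        rate * 9.0 * medium.viscosity / (4.0 * phi * (k * species.radius) ** 2)
    )


def _stable_arctan_exp(s: np.ndarray) -> np.ndarray:
    """``arctan(exp(s))`` without overflow for large s."""
    a = np.arctan(np.exp(-np.abs(s)))
    return np.where(s > 0.0, np.pi / 2.0 - a, a)


def _path_fit_rate(traj: Trajectory, k: float, node: float, width: float,
                   exclude_margin: float) -> float:
    """Growth rate of tan(k y) by nonlinear LSQ of the path in position space."""
    from scipy.optimize import least_squares

    y, t = traj.y, traj.t
    lower = y[0] <= node
    sign = 1.0 if lower else -1.0
    offset = 0.0 if lower else width
    yf = y if lower else width - y
    # initial guess from the log-tan slope on safely interior samples
    safe = (yf > exclude_margin) & (yf < node - exclude_margin)
    if np.count_nonzero(safe) >= 3:
        coef = np.polyfit(
            t[safe], np.log(np.tan(k * np.clip(yf[safe], 1e-12, node - 1e-12))), 1
        )
        theta0, rate0 = float(coef[1]), max(float(coef[0]), 1e-3)
    else:
        y0 = min(max(float(yf[0]), 1e-9), 0.99 * node)
        theta0, rate0 = math.log(math.tan(k * y0)), 1.0

    def residuals(params):
        theta, log_rate = params
        y_model = offset + sign * _stable_arctan_exp(theta + np.exp(log_rate) * t) / k
        return y_model - y

    fit = least_squares(residuals, [theta0, math.log(rate0)], method="lm")
    if not fit.success:
        raise EstimationError(f"particle {traj.particle_id}: path fit did not converge")
    return float(np.exp(fit.x[1]))


def estimate_per_particle(
    traj: Trajectory,
    species: ParticleSpecies,
    medium: Medium,
    field: DriveField,
    geometry: ResonatorGeometry,
    method: str = "path",
    exclude_margin: float = DEFAULT_EXCLUDE_MARGIN,
) -> float:
    """Energy density (J/m^3) from one tracked path.

    See the module docstring for the three methods; all agree on noiseless
    closed-form paths.
    """
    if len(traj) < 3:
        raise EstimationError(f"particle {traj.particle_id}: fewer than 3 samples")
    k = field.wavenumber
    width = math.pi / k
    node = width / 2.0
    if method == "path":
        rate = _path_fit_rate(traj, k, node, width, exclude_margin)
        return _rate_to_eac(rate, species, medium, k)
    t, yf = _fit_window(traj, k, node, width, exclude_margin)
    if t.size < 3:
        raise EstimationError(
            f"particle {traj.particle_id}: fewer than 3 usable samples "
            "after node/wall exclusion"
        )
    if method == "endpoints":
        if abs(yf[-1] - node) > abs(yf[0] - node):
            raise EstimationError(
                f"particle {traj.particle_id}: net motion away from the node"
            )
        return energy_density_from_displacement(
            yf[0], yf[-1], t[-1] - t[0], species, medium, field
        )
    if method != "regression":
        raise ValueError(f"unknown method {method!r}")
    slope = np.polyfit(t, np.log(np.tan(k * yf)), 1)[0]
    return _rate_to_eac(float(slope), species, medium, k)


def estimate_energy_density(
    trajectories: list[Trajectory],
    species: ParticleSpecies,
    medium: Medium,
    field: DriveField,
    geometry: ResonatorGeometry,
    method: str = "path",
    exclude_margin: float = DEFAULT_EXCLUDE_MARGIN,
    ensemble: str = "per_particle",
) -> EnergyDensityEstimate:
    """Ensemble estimate: per-path energy densities, mean +/- std.

    ``ensemble="per_particle"`` (default) averages per-path estimates —
    this is what yields a meaningful spread across particles.
    ``ensemble="coordinate_mean"`` first averages the folded coordinate
    lists across particles on their common time grid, then fits once.
    """
    if not trajectories:
        raise EstimationError("no trajectories supplied")
    if ensemble == "coordinate_mean":
        return _estimate_coordinate_mean(
            trajectories, species, medium, field, geometry, exclude_margin
        )
    if ensemble != "per_particle":
        raise ValueError(f"unknown ensemble method {ensemble!r}")
    values: dict[str, float] = {}
    rejected: dict[str, str] = {}
    for traj in trajectories:
        try:
            values[traj.particle_id] = estimate_per_particle(
                traj, species, medium, field, geometry,
                method=method, exclude_margin=exclude_margin,
            )
        except EstimationError as exc:
            rejected[traj.particle_id] = str(exc)
    if not values:
        raise EstimationError(
            "all trajectories rejected: "
            + "; ".join(f"{k}: {v}" for k, v in rejected.items())
        )
    arr = np.array(list(values.values()))
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return EnergyDensityEstimate(
        mean=mean,
        std=std,
        per_particle=values,
        n=arr.size,
        pressure_amplitude=pressure_amplitude(max(mean, 0.0), medium),
        rejected=rejected,
    )


def _estimate_coordinate_mean(
    trajectories, species, medium, field, geometry, exclude_margin
) -> EnergyDensityEstimate:
    k = field.wavenumber
    width = math.pi / k
    node = width / 2.0
    # fold every track to the lower half-channel, average ln tan(k y) on the
    # intersection of their fit windows, then fit one slope
    series = []
    for traj in trajectories:
        t, yf = _fit_window(traj, k, node, width, exclude_margin)
        if t.size >= 3:
            series.append((t, np.log(np.tan(k * yf))))
    if not series:
        raise EstimationError("no usable trajectories for coordinate averaging")
    t_common = series[0][0]
    for t, _ in series[1:]:
        t_common = np.intersect1d(t_common, t)
    if t_common.size < 3:
        raise EstimationError("fewer than 3 common time points across trajectories")
    stacked = np.array(
        [np.interp(t_common, t, v) for t, v in series]
    )
    slope = np.polyfit(t_common, stacked.mean(axis=0), 1)[0]
    phi = contrast_factor(species, medium)
    mean = float(
        slope * 9.0 * medium.viscosity / (4.0 * phi * (k * species.radius) ** 2)
    )
    return EnergyDensityEstimate(
        mean=mean,
        std=0.0,
        per_particle={},
        n=len(series),
        pressure_amplitude=pressure_amplitude(max(mean, 0.0), medium),
    )
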