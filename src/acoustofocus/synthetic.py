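"""Synthetic stand-ins for the experimental time-lapse observables.

No tracked-bead recordings are deposited with the study, so every stage of
the analysis is exercised on generated data with the statistical structure
the method assumes: transverse tracks that follow the closed-form
acoustophoretic path sampled at the acquisition cadence of the 4x-objective
time-lapses (500 ms frames over 2 minutes, 1.63 um/pixel), pixel-quantised
with Gaussian localisation noise; uniform inlet ensembles for the transport
simulations; and noisy absorbance-style readout pairs standing in for the
outlet UV-Vis ratio.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import DriveField, ResonatorGeometry, transverse_path
from .materials import Medium, ParticleSpecies
from .simulate import OutletPartition

__all__ = [
    "AcquisitionSpec",
    "generate_trajectories",
    "generate_inlet_ensemble",
    "generate_outlet_readout",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Time-lapse acquisition parameters of the tracking experiment."""

    frame_interval: float = 0.5  # s
    duration: float = 120.0  # s
    pixel_size: float = 1.63e-6  # m/pixel (4x objective)
    noise_px: float = 1.0  # localisation noise sigma, pixels
    n_particles: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0.0 or self.duration <= 0.0:
            raise ValueError("frame interval and duration must be positive")
        if self.pixel_size <= 0.0:
            raise ValueError("pixel size must be positive")
        if self.noise_px < 0.0:
            raise ValueError("noise level must be non-negative")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.n_frames < 3:
            raise ValueError("duration/frame_interval must yield at least 3 frames")

    @property
    def n_frames(self) -> int:
        """Frames per track, including the initial frame."""
        return int(round(self.duration / self.frame_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def generate_trajectories(
    true_eac: float,
    species: ParticleSpecies,
    medium: Medium,
    field: DriveField,
    geometry: ResonatorGeometry,
    acq: AcquisitionSpec,
    seed: int | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Synthetic tracked transverse paths at a known energy density.

    Initial positions are uniform over
    ``(0.05 w, 0.45 w) U (0.55 w, 0.95 w)`` — tracked beads start near the
    walls and move inward, and the node band is excluded.  True positions
    follow the closed-form path at ``true_eac``, then Gaussian localisation
    noise is added and positions are quantised to the pixel grid.

    Returns a DataFrame with columns ``particle_id, t, y`` (SI units, the
    loader schema).  When ``path`` is given, writes ``<path>`` as CSV plus a
    JSON manifest ``<path>.manifest.json`` recording all parameters.
    """
    if true_eac < 0.0:
        raise ValueError("true_eac must be non-negative")
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    w = geometry.width
    # uniform over the two off-node, off-wall bands
    u = rng.uniform(0.0, 0.8, size=acq.n_particles)
    y0 = np.where(u < 0.4, 0.05 * w + u * w, 0.55 * w + (u - 0.4) * w)
    t = acq.times
    eac_field = dataclasses.replace(
        field, energy_density=true_eac, pressure_amplitude=None
    )
    y_true = transverse_path(y0[:, None], t[None, :], species, medium, eac_field)
    noise = rng.normal(0.0, acq.noise_px * acq.pixel_size, size=y_true.shape)
    y_obs = np.round((y_true + noise) / acq.pixel_size) * acq.pixel_size
    y_obs = np.clip(y_obs, 0.0, w)

    frames = [
        pd.DataFrame({"particle_id": f"p{i:03d}", "t": t, "y": y_obs[i]})
        for i in range(acq.n_particles)
    ]
    df = pd.concat(frames, ignore_index=True)

    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False)
        manifest = {
            "true_eac_j_m3": true_eac,
            "species": dataclasses.asdict(species),
            "medium": dataclasses.asdict(medium),
            "frequency_hz": field.frequency,
            "geometry": dataclasses.asdict(geometry),
            "acquisition": dataclasses.asdict(acq),
            "seed": int(acq.seed if seed is None else seed),
            "columns": {"t": "s", "y": "m"},
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )
    return df


def generate_inlet_ensemble(
    n: int, geometry: ResonatorGeometry, seed: int = 0
) -> np.ndarray:
    """Uniform entry positions over the inlet cross-section, shape (n, 2)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    out[:, 0] = rng.uniform(0.0, geometry.width, size=n)
    out[:, 1] = rng.uniform(0.0, geometry.height, size=n)
    return out


def generate_outlet_readout(
    partition: OutletPartition,
    noise_cv: float = 0.05,
    seed: int = 0,
    label: str | None = None,
) -> tuple[float, float]:
    """Absorbance-style proxy readouts (central, side) for an outlet tally.

    Readouts are proportional to counts with multiplicative lognormal noise
    of coefficient of variation ``noise_cv``, mean-corrected so the expected
    readout equals the count.  The ratio central/(central+side) of the
    returned pair is the UV-Vis-style focusing fraction.
    """
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be non-negative")
    if label is None:
        central = sum(partition.central.values())
        side = sum(partition.side.values())
    else:
        central = partition.central[label]
        side = partition.side[label]
    if central < 0 or side < 0:
        raise ValueError("counts must be non-negative")
    if noise_cv == 0.0:
        return float(central), float(side)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=2)
    return float(central * factors[0]), float(side * factors[1])
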