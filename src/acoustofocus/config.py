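"""Run configuration: YAML/JSON schema with explicit unit suffixes.

Physical quantities in config files carry their unit in the key name
(``flow_rate_ul_min``, ``width_um``, ...) and are converted to SI at parse
time; everything in memory is SI.  Every section has device defaults, so an
empty config describes the reference resonator (190 x 95 um x 40 mm
channel, water at 20 degC, polystyrene tracer beads).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import yaml

from .acoustics import DriveField, KAPPA_V_DEFAULT, ResonatorGeometry
from .materials import (
    POLYSTYRENE_COMPRESSIBILITY,
    POLYSTYRENE_DENSITY,
    Medium,
    ParticleSpecies,
)
from .synthetic import AcquisitionSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration failed schema validation; the message names the field."""


@dataclass
class SimulationControls:
    flow_rate_ul_min: float = 3.0
    dt_s: float = 1e-3
    duration_s: float = 1.0
    t_max_s: float = 600.0
    n_particles: int = 200
    seed: int = 0
    streaming: bool = False


@dataclass
class RunConfig:
    medium: Medium
    species: list[ParticleSpecies]
    geometry: ResonatorGeometry
    drive_frequency_hz: float | None
    energy_density_j_m3: float | None
    vpp_v: float | None
    kappa_v: float
    simulation: SimulationControls
    acquisition: AcquisitionSpec
    output_dir: Path = Path("results")

    def drive_field(self) -> DriveField:
        """The half-wave transverse mode of the configured channel."""
        if self.energy_density_j_m3 is not None:
            return DriveField.half_wave(
                self.geometry, self.medium, energy_density=self.energy_density_j_m3
            )
        if self.vpp_v is not None:
            return DriveField.half_wave(
                self.geometry, self.medium, vpp=self.vpp_v, kappa_v=self.kappa_v
            )
        raise ConfigError("drive: set either energy_density_j_m3 or vpp_v")

    def config_hash(self) -> str:
        payload = {
            "medium": dataclasses.asdict(self.medium),
            "species": [dataclasses.asdict(s) for s in self.species],
            "geometry": dataclasses.asdict(self.geometry),
            "drive_frequency_hz": self.drive_frequency_hz,
            "energy_density_j_m3": self.energy_density_j_m3,
            "vpp_v": self.vpp_v,
            "kappa_v": self.kappa_v,
            "simulation": dataclasses.asdict(self.simulation),
            "acquisition": dataclasses.asdict(self.acquisition),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _section(raw: dict, name: str) -> dict:
    value = raw.get(name, {})
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"{name}: expected a mapping")
    return value


def _pop_float(section: dict, section_name: str, key: str, default):
    value = section.pop(key, default)
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{section_name}.{key}: expected a number, got {value!r}")


def _reject_unknown(section: dict, name: str) -> None:
    if section:
        raise ConfigError(f"{name}: unknown key(s) {sorted(section)}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse a YAML or JSON config file; missing sections take device defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level: expected a mapping")
    if overrides:
        raw = {**raw, **overrides}

    med = _section(raw, "medium")
    medium = Medium(
        density=_pop_float(med, "medium", "density_kg_m3", 998.0),
        sound_speed=_pop_float(med, "medium", "sound_speed_m_s", 1481.0),
        viscosity=_pop_float(med, "medium", "viscosity_pa_s", 1.002e-3),
        compressibility=_pop_float(med, "medium", "compressibility_1_pa", None),
        name=str(med.pop("name", "medium")),
    )
    _reject_unknown(med, "medium")

    species_raw = raw.get("species") or [{}]
    if not isinstance(species_raw, list):
        raise ConfigError("species: expected a list of mappings")
    species = []
    for i, item in enumerate(species_raw):
        if not isinstance(item, dict):
            raise ConfigError(f"species[{i}]: expected a mapping")
        item = dict(item)
        diameter = _pop_float(item, f"species[{i}]", "diameter_um", 4.0)
        sp = ParticleSpecies(
            radius=diameter * 1e-6 / 2.0,
            density=_pop_float(item, f"species[{i}]", "density_kg_m3", POLYSTYRENE_DENSITY),
            compressibility=_pop_float(
                item, f"species[{i}]", "compressibility_1_pa", POLYSTYRENE_COMPRESSIBILITY
            ),
            label=str(item.pop("label", f"species-{i}")),
        )
        _reject_unknown(item, f"species[{i}]")
        species.append(sp)

    geo = _section(raw, "geometry")
    geometry = ResonatorGeometry(
        width=_pop_float(geo, "geometry", "width_um", 190.0) * 1e-6,
        height=_pop_float(geo, "geometry", "height_um", 95.0) * 1e-6,
        length=_pop_float(geo, "geometry", "length_mm", 40.0) * 1e-3,
        central_band_fraction=_pop_float(
            geo, "geometry", "central_band_fraction", 1.0 / 3.0
        ),
    )
    _reject_unknown(geo, "geometry")

    drv = _section(raw, "drive")
    frequency_mhz = _pop_float(drv, "drive", "frequency_mhz", None)
    energy_density = _pop_float(drv, "drive", "energy_density_j_m3", None)
    vpp = _pop_float(drv, "drive", "vpp_v", None)
    kappa_v = _pop_float(drv, "drive", "kappa_v", KAPPA_V_DEFAULT)
    _reject_unknown(drv, "drive")
    if energy_density is None and vpp is None:
        energy_density = 7.25

    sim = _section(raw, "simulation")
    simulation = SimulationControls(
        flow_rate_ul_min=_pop_float(sim, "simulation", "flow_rate_ul_min", 3.0),
        dt_s=_pop_float(sim, "simulation", "dt_s", 1e-3),
        duration_s=_pop_float(sim, "simulation", "duration_s", 1.0),
        t_max_s=_pop_float(sim, "simulation", "t_max_s", 600.0),
        n_particles=int(sim.pop("n_particles", 200)),
        seed=int(sim.pop("seed", 0)),
        streaming=bool(sim.pop("streaming", False)),
    )
    _reject_unknown(sim, "simulation")

    acq = _section(raw, "acquisition")
    acquisition = AcquisitionSpec(
        frame_interval=_pop_float(acq, "acquisition", "frame_interval_s", 0.5),
        duration=_pop_float(acq, "acquisition", "duration_s", 120.0),
        pixel_size=_pop_float(acq, "acquisition", "pixel_size_um", 1.63) * 1e-6,
        noise_px=_pop_float(acq, "acquisition", "noise_px", 1.0),
        n_particles=int(acq.pop("n_particles", 20)),
        seed=int(acq.pop("seed", 0)),
    )
    _reject_unknown(acq, "acquisition")

    output_dir = Path(raw.get("output_dir", "results"))

    known = {
        "medium", "species", "geometry", "drive", "simulation",
        "acquisition", "output_dir",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"top level: unknown section(s) {sorted(unknown)}")

    return RunConfig(
        medium=medium,
        species=species,
        geometry=geometry,
        drive_frequency_hz=frequency_mhz * 1e6 if frequency_mhz else None,
        energy_density_j_m3=energy_density,
        vpp_v=vpp,
        kappa_v=kappa_v,
        simulation=simulation,
        acquisition=acquisition,
        output_dir=output_dir,
    )
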