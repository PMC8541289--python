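# acoustofocus

Modelling toolkit for acoustophoretic particle focusing in a bulk-acoustic-wave
(BAW) transversal resonator — the silicon microchannel geometry in which an
ultrasonic standing wave spans the channel width, a pressure node forms along
the channel centre, and suspended microparticles or cells with positive
acoustic contrast migrate to that node and can be collected at a central
outlet. It is written for microfluidics researchers who want to design such a
channel, predict which particle sizes it can separate, and extract the
acoustic energy density of a running device from video-tracked bead paths.

## Physics

A spherical particle of radius $a_0$, volume $V_p$, density $\rho_p$ and
compressibility $\beta_p$ suspended in a fluid ($\rho_m,\ \beta_m,\ \eta_m,\ c_m$)
inside a half-wave standing wave ($\lambda = 2 w_{ch}$, wavenumber
$k = \pi / w_{ch}$) experiences the primary radiation force

$$F_R = -\frac{\pi p_0^2 V_p \beta_m}{2\lambda}\,\phi\,\sin\!\frac{4\pi x}{\lambda},
\qquad
\phi = \frac{5\rho_p - 2\rho_m}{2\rho_p + \rho_m} - \frac{\beta_p}{\beta_m},$$

with $x$ the distance from the pressure node. Balancing $F_R$ against Stokes
drag $F_D = -6\pi\eta_m a_0 v_p$ gives the closed-form transverse path

$$y(t) = \frac{1}{k}\arctan\!\Big\{\tan[k\,y(0)]\,
\exp\!\Big[\frac{4\phi}{9\eta_m}(k a_0)^2 E_{ac}\,t\Big]\Big\},$$

whose inversion estimates the acoustic energy density $E_{ac}$ (J/m³) from a
tracked $(t, y)$ path; the in-channel pressure amplitude follows from
$p_a = 2 c_m \sqrt{E_{ac}\rho_m}$. Boundary-layer (Rayleigh) streaming is
modelled with the limiting-velocity method: the analytic first-order field
yields an effective wall slip $-(3/8)(U^2/c_m)\sin 2ky$ that drives a Stokes
flow in the cross-section, and the competition between streaming drag and
radiation force sets the critical particle diameter
$2a_0 = \sqrt{27\eta_m / (2\pi\phi\rho_m f)}$ below which node focusing fails.

## Layout

- `src/acoustofocus/` — the library: `materials` (fluid/particle properties),
  `acoustics` (closed forms above), `streaming` (limiting-velocity Stokes
  solve), `flow` (rectangular-duct Poiseuille profile), `simulate`
  (overdamped ensemble transport and focusing metrics), `energy`
  (track-based energy-density estimator), `synthetic` (seeded generators for
  time-lapse-like tracks), `config`/`cli` (YAML config and command line).
- `analysis/01_design_calculations.py` … `04_focusing_study.py` — the
  numbered study drivers; each prints what it finds and writes JSON/CSV
  tables under `results/`.
- `tests/` — the pytest suite, including end-to-end acceptance checks.

## Worked example

Estimate the acoustic energy density from synthetic tracked bead paths, the
same pipeline you would run on CSV exports from video-tracking software:

```python
import acoustofocus as af

water = af.WATER_20C
geom = af.ResonatorGeometry()            # 190 x 95 um, 40 mm channel
bead = af.polystyrene_sphere(4e-6, "4MP")
field = af.DriveField.half_wave(geom, water, energy_density=7.25)

df = af.generate_trajectories(7.25, bead, water, field, geom,
                              af.AcquisitionSpec(), seed=1)
tracks = [af.Trajectory(str(p), g["t"].to_numpy(), g["y"].to_numpy())
          for p, g in df.groupby("particle_id")]
est = af.estimate_energy_density(tracks, bead, water, field, geom)
print(f"E_ac = {est.mean:.2f} +/- {est.std:.2f} J/m^3 "
      f"-> p_a = {est.pressure_amplitude/1e6:.3f} MPa")
```

```
E_ac = 7.40 +/- 0.83 J/m^3 -> p_a = 0.254 MPa
```

Twenty 2-minute tracks at 500 ms frame interval with 1-pixel (1.63 µm)
localisation noise recover the generating energy density of 7.25 J/m³ within
a few percent; the attached pressure amplitude is the ≈0.25 MPa standing-wave
amplitude such a drive produces in water. The same estimator accepts real
tracker exports via `af.load_trajectories(path, length_unit="px",
pixel_size=1.63e-6)`.

The command line mirrors the library:
`acoustofocus design`, `acoustofocus synth`, `acoustofocus estimate`,
`acoustofocus simulate`, `acoustofocus streaming` (see `--help`).

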