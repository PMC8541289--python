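# Methods

This note records the model, its assumptions, the defaults, and the design
choices made where more than one defensible reading existed. Symbols follow
the README.

## Coordinate frame and the standing-wave mode

The transverse coordinate `y` runs from the left channel wall (`y = 0`) to
the right wall (`y = w_ch`); the vertical coordinate `z` spans the channel
depth and `x` the axial length. The resonator operates on its first
transverse mode: pressure anti-nodes at the walls, a single node at
`y = w_ch/2`, wavelength `lambda = 2 w_ch`, wavenumber `k = pi/w_ch`. All
closed forms (`tan(k y)` path, radiation force, slip profile) are
single-branch on the lower half-channel `(0, w_ch/2]`; the upper half is
mapped by reflection about the node. This makes the path and its inversion
single-valued, and is the reason the estimator folds tracks onto one
half-channel before fitting.

A real loaded resonator does not satisfy the ideal half-wave relation
exactly: for the fabricated 190 µm channel the geometric mode lies at
`c_m/(2 w_ch) = 3.90 MHz` in 20 °C water while the measured resonance of the
assembled device is 4.623 MHz. The package keeps `DriveField` internally
consistent (`lambda = c_m/f` always) and provides `DriveField.half_wave`,
which pins the field to the channel's geometric mode; every in-channel
operation requires that configuration. The experimental drive frequency is
used only where frequency is a free input — the critical-diameter scaling
and the design-width calculator. Because track generation and estimation
always share one field, energy-density round trips are independent of this
choice.

## Parameters and defaults

| parameter | default | unit | note |
|---|---|---|---|
| water density / sound speed / viscosity | 998 / 1481 / 1.002e-3 | kg/m³, m/s, Pa·s | 20 °C; compressibility auto-derived as `1/(rho c^2)` = 4.57e-10 1/Pa |
| polystyrene density / compressibility | 1050 / 2.16e-10 | kg/m³, 1/Pa | gives contrast factor φ ≈ 0.578 in water |
| channel w × h × L | 190 × 95 µm × 40 mm | m | fabricated geometry |
| central band / outlet fraction | 1/3 | — | width of the node collection band |
| voltage calibration κ_V | 7.25/52.92² ≈ 2.589e-3 | J/m³/V² | anchors 52.92 Vpp ↦ 7.25 J/m³; energy density scales with drive amplitude squared |
| acquisition | 0.5 s frames, 120 s, 1.63 µm/px, σ = 1 px, 20 tracks | — | the time-lapse tracking configuration |
| integrator step | 1 ms (1–10 ms used in ensemble studies) | s | RK4; adaptive halving keeps per-step transverse motion < w_ch/100 |

The localisation noise default of one pixel is a choice: the acquisition
pixel scale is documented but the tracking error of the video software is
not, and one pixel is a typical centroid accuracy for few-pixel beads. It is
exposed in `AcquisitionSpec`.

## Readings of ambiguous closed forms

Three printed formulas in the source material admit more than one reading;
the implemented readings were fixed by internal consistency, not by fitting:

- **Radiation-force prefactor.** The force is implemented with the *medium*
  compressibility in the prefactor, `pi p0^2 V_p beta_m / (2 lambda)`. With
  `E_ac = p0^2 beta_m / 4` this is algebraically identical to
  `V_p k E_ac phi sin(2kx)`, which is the only form dimensionally consistent
  with the closed-form path; the package asserts this identity to 1e-12.
- **Pressure amplitude.** Implemented as `p_a = sqrt(4 E_ac rho_m c_m^2)`,
  i.e. `E_ac = p_a^2/(4 rho_m c_m^2)`; this reproduces the reference
  7.25 J/m³ → 0.252 MPa conversion.
- **Critical diameter.** Implemented as the diameter at which the peak
  acoustophoretic velocity `2 phi k a^2 E_ac / (9 eta_m)` equals the peak
  Rayleigh slip `(3/8) U^2/c_m` (with `U^2 = 4 E_ac/rho_m`; the energy
  density cancels): `2a_0 = sqrt(27 eta_m/(2 pi phi rho_m f))`. For the
  device this gives ≈1.3 µm at 4.623 MHz — micrometre-scale, consistent with
  the observed failure to collect 0.5–1 µm particles, and verified in the
  tests against a numerical force balance on the streaming module's own slip
  field. Published tabulations of this cutoff vary by O(1) constants with
  the geometry factor and contrast convention; the value here is the one
  consistent with this package's own force and streaming models.

## Streaming model

The second-order time-averaged flow is computed with the limiting-velocity
(slip) method: the viscous boundary layer is not resolved; its rectified
effect is condensed into an effective tangential wall velocity computed from
the first-order field, with each limiting-velocity component pairing the
first-order velocity with its own complex conjugate. For the analytic
transverse mode the slip reduces to the classical Rayleigh value
`-(3/8)(U^2/c) sin(2ky)` on the top and bottom walls (verified to < 1%) and
vanishes on the side walls.

The bulk Stokes problem is solved on the rectangular cross-section in
streamfunction–vorticity form, assembled as one sparse linear system
(`lap psi + omega = 0`, `lap omega = 0`, psi = 0 on walls, Thom-type wall
vorticity carrying the slip) and solved directly. Velocities are recovered
by central differences of psi, so the discrete divergence vanishes
identically at interior nodes (machine level, asserted). The second-order
pressure is integrated from the vorticity gradient (curl-free because
`lap omega = 0`). Wall-tangential velocity matches the imposed slip to the
one-sided-difference accuracy of the wall closure (≈2% at 128×64). The
observed grid convergence of the roll velocity is ~2nd order.

The first-order field is analytic rather than a finite-element solve with an
actuated-wall boundary condition; this keeps the slip formulas exact, and
every closed-form result in the package already assumes the ideal mode.
Boundary-layer-resolving simulation, thermoviscous corrections and 3-D
axial streaming are out of scope.

## Transport simulation

Particles are overdamped point spheres: transverse velocity = radiation
force / Stokes drag + streaming velocity; vertical velocity = streaming;
axial velocity = the rectangular-duct Poiseuille profile (Fourier series, 11
odd terms, numerically rescaled so the flux equals the volumetric flow rate
exactly). RK4 with global adaptive halving integrates `(y, z)`; the axial
coordinate advances with the midpoint transverse position (2nd order).
Entries are uniform over the inlet cross-section; ensembles are pure
functions of their seed. Inter-particle forces, wall lift, radiation torque
and cell deformability are not modelled, and mixtures are transported as
independent species.

Two focusing metrics mirror the two experimental characterisations:

- **Outlet metric** — central-outlet count over total exited, tallied at the
  moment each particle crosses the exit plane.
- **Band (image) metric** — fraction of transverse positions within the
  central 1/3 band.

For sub-critical species under streaming the outlet metric conditioned on
exit is flux-weighted (the parabolic profile over-samples the channel
centre; a uniform suspension already yields ≈0.48 at the central outlet
band, not 1/3), so the critical-size behaviour is assessed with the band
metric on a cross-section ensemble insonated for the 120 s time-lapse
window without axial flow — the stop-flow configuration of the tracking
experiment. There the signature is clean: supercritical 4 µm beads collect
fully (band fraction 1.0) while 1 µm and 0.5 µm species end near the uniform
1/3 occupancy. Sub-critical species show a transient: radiation initially
drifts them nodeward (band fractions up to ~0.7 at 15–40 s) before the
streaming rolls wrap the distribution back toward uniform — qualitatively
the same intermediate focusing percentages reported for micron-scale
particles in this device class.

The simulated focusing fraction of supercritical beads saturates near 1.0
across the experimental flow-rate range: a single-particle model has no
concentration dependence, and the experimentally observed decline at high
concentration (inter-particle interactions, node saturation) is explicitly
not modelled. The monotone trends (non-increasing in flow rate,
non-decreasing in drive voltage) are exact under shared entry positions
because each particle's dynamics is monotone in exposure time and energy
density.

## Energy-density estimation

Each tracked path yields one estimate of `E_ac` through the growth rate of
`tan(k y(t))`. Three per-path methods:

- `path` (default): nonlinear least squares of the closed-form path in
  *position* space. Localisation noise is additive in position, so the fit
  is unbiased even when a path saturates at the node within a few frames; it
  uses every frame and needs no sample exclusion. Bias measured at the
  acquisition defaults: −0.2% (50 replicates), with ≥90% coverage of the
  mean ± 2 SE interval.
- `regression`: ordinary least-squares slope of `ln tan(k y)` vs `t` over
  the pre-arrival window, excluding samples within 2 pixels of the node or a
  wall (`tan` degeneracy). Transparent and exact on noiseless data, but the
  node-side exclusion selects against upward noise excursions, leaving a
  ≈−8% bias when only 4–6 frames precede node arrival (the situation at the
  reference energy density); it is accurate when tracks span tens of frames.
- `endpoints`: the literal two-point displacement inversion.

Ensemble summary is per-particle mean ± sample standard deviation (this is
what produces a meaningful across-particle spread); averaging the folded
coordinates first and fitting once is available as
`ensemble="coordinate_mean"`. Tracks whose usable window is shorter than
3 samples are rejected per particle with a reason, never silently.

## What the synthetic data does and does not emulate

The generator produces exactly the structure the estimator assumes: paths
following the closed form at a known energy density, sampled at the
acquisition cadence, pixel-quantised, with i.i.d. Gaussian localisation
noise, and initial positions drawn outside the node band and the extreme 5%
near the walls (tracked beads start near the walls and move inward). It does
not emulate tracking failures (broken/swapped tracks), out-of-plane motion,
particle–particle interactions, flow disturbances, or non-Gaussian tails of
real centroid errors. Passing recovery tests therefore demonstrates the
correctness and noise robustness of the inference given the model, not the
fidelity of any specific tracking software.

## Numerical choices and degenerate inputs

- Anti-node starting positions (`y0` exactly 0 or `w_ch`) are unstable
  equilibria: returned unchanged with a warning, so population runs never
  abort.
- Path evaluation works in `ln tan` space (`exp`/`arctan` composed stably),
  so saturation at the node cannot overflow.
- Displacement inversion rejects endpoints exactly at walls or node and
  motion away from the node; a zero displacement returns exactly 0.
- Injection-rate conversion uses the ceiling (a fractional arrival rate
  becomes a whole per-second count), with a 1e-9 guard against float
  round-up of exact integers.
- The integrator halves its step (cap: 20 halvings, then an error) whenever
  any particle would move more than `w_ch/100` transversely in one step.
- Problem sizes in the study drivers and tests — 200-particle ensembles,
  128×64 streaming grids, 10 estimation replicates — were chosen as the
  smallest sizes at which the reported fractions are stable to well within
  their binomial error; all are parameters, not limits.

## Known limitations

- The analytic mode ignores wall compliance; absolute streaming magnitudes
  in a real device depend on the actuation details the model omits.
- The critical-diameter constant is convention-dependent (see above);
  treat the ≈1.3 µm figure as internally consistent rather than universal.
- Energy-density estimates inherit the calibration of `k`: a device whose
  true transverse wavenumber deviates from `pi/w_ch` scales the recovered
  `E_ac` by the square of that deviation.
- The phenomenological concentration dependence of focusing is not modelled;
  the package reproduces trends in flow rate, voltage and size only.
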