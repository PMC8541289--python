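#!/usr/bin/env python
"""Monte-Carlo focusing study of the resonator.

Reproduces the numerical transport experiments: per-second injection counts
for the stock concentrations, central-outlet collection versus flow rate
and drive voltage for 4 um beads (200 particles per condition, fixed
entries), and the critical-size study with streaming drag enabled over the
2-minute insonation window.  Writes results/focusing_study.json.
"""

import json
from pathlib import Path

import acoustofocus as af

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

water = af.WATER_20C
geometry = af.ResonatorGeometry()
bead4 = af.polystyrene_sphere(4e-6, "4MP")
results: dict = {}

print("== injection rates at 3 uL/min ==")
results["injection_rates_per_s"] = {
    f"{c:.3g}_per_ml": af.injection_rate(c, 3.0) for c in (5.68e6, 1.14e6, 5.68e5)
}
for key, rate in results["injection_rates_per_s"].items():
    print(f"  {key}: {rate} /s")

print("\n== outlet collection vs flow rate (4 um, 50.59 Vpp) ==")
field_op = af.DriveField.half_wave(geometry, water, vpp=50.59)
flow_sweep = {}
for q in (1.0, 3.0, 10.0):
    _, rep = af.simulate_population(
        [bead4], water, field_op, geometry,
        flow_rate_ul_min=q, n_particles=200, seed=7, dt=0.01, t_max=600.0,
    )
    flow_sweep[f"{q:g}_ul_min"] = rep["4MP"].outlet_fraction
    print(f"  {q:4g} uL/min: {rep['4MP'].outlet_fraction:.3f}")
results["outlet_fraction_vs_flow"] = flow_sweep

print("\n== outlet collection vs drive voltage (4 um, 3 uL/min) ==")
vpp_sweep = {}
for vpp in (12.65, 25.29, 37.95, 50.59, 56.92):
    field = af.DriveField.half_wave(geometry, water, vpp=vpp)
    _, rep = af.simulate_population(
        [bead4], water, field, geometry,
        flow_rate_ul_min=3.0, n_particles=200, seed=7, dt=0.01, t_max=400.0,
    )
    vpp_sweep[f"{vpp:g}_v"] = rep["4MP"].outlet_fraction
    print(f"  {vpp:5.2f} Vpp (E_ac {field.energy_density:5.2f} J/m^3): "
          f"{rep['4MP'].outlet_fraction:.3f}")
results["outlet_fraction_vs_vpp"] = vpp_sweep

print("\n== critical-size study with streaming drag (120 s insonation) ==")
f1 = af.first_order_field(field_op, geometry, (128, 64))
sol = af.solve_streaming(af.limiting_velocity(f1), geometry, water)
critical = {}
for d, label in ((4e-6, "4MP"), (1e-6, "1MP"), (0.5e-6, "NP")):
    sp = af.polystyrene_sphere(d, label)
    y, _ = af.simulate_crosssection(
        sp, water, field_op, geometry, n_particles=200, duration=120.0,
        seed=11, streaming=sol, dt=0.01,
    )
    frac = af.focusing_fraction_band(y, geometry)
    critical[label] = frac
    print(f"  {label:4s} ({d * 1e6:g} um): band fraction {frac:.3f}")
results["band_fraction_with_streaming_120s"] = critical
print("-> the 4 um species collects fully; sub-micron species hover near the")
print("   uniform 1/3 occupancy, the signature of sub-critical transport.")

(OUT / "focusing_study.json").write_text(json.dumps(results, indent=2))
print(f"\nwrote {OUT / 'focusing_study.json'}")
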