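#!/usr/bin/env python
"""Closed-form design study of the transversal resonator.

Computes the half-wavelength design width over the transducer's frequency
range, the acoustic contrast factors and critical diameter of the bead
species, and the energy-density -> pressure-amplitude map.  Writes
results/design.json.
"""

import json
from pathlib import Path

import acoustofocus as af

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

water = af.WATER_20C
geometry = af.ResonatorGeometry()
species = {
    "4MP": af.polystyrene_sphere(4e-6, "4MP"),
    "1MP": af.polystyrene_sphere(1e-6, "1MP"),
    "NP": af.polystyrene_sphere(0.5e-6, "NP"),
}

print("== half-wavelength design width ==")
widths = {}
for f_mhz in (4.0, 4.623, af.DriveField.half_wave(geometry, water).frequency / 1e6):
    w = af.design_width(water, f_mhz * 1e6)
    widths[f"{f_mhz:.3f}_mhz"] = w
    print(f"  f = {f_mhz:7.3f} MHz -> w_ch = {w * 1e6:7.2f} um")
print(f"  (fabricated channel: {geometry.width * 1e6:.0f} um; the geometric")
print("   half-wave mode of that width lies at "
      f"{water.sound_speed / (2 * geometry.width) / 1e6:.3f} MHz)")

print("\n== contrast factors and critical diameter ==")
contrast = {}
for label, sp in species.items():
    phi = af.contrast_factor(sp, water)
    contrast[label] = phi
    print(f"  {label}: phi = {phi:.4f}")
dcrit = af.critical_diameter(contrast["4MP"], water, 4.623e6)
print(f"  critical diameter at 4.623 MHz: {dcrit * 1e6:.2f} um")
print("  -> 4 um beads are supercritical; 0.5-1 um species are not collected")

print("\n== energy density -> pressure amplitude ==")
pa_map = {}
for eac in (1.0, 2.0, 5.0, 7.25, 10.0):
    pa = af.pressure_amplitude(eac, water)
    pa_map[str(eac)] = pa
    print(f"  E_ac = {eac:5.2f} J/m^3 -> p_a = {pa / 1e6:.3f} MPa")

(OUT / "design.json").write_text(
    json.dumps(
        {
            "design_width_m": widths,
            "contrast_factors": contrast,
            "critical_diameter_m_at_4p623_mhz": dcrit,
            "pressure_amplitude_pa": pa_map,
        },
        indent=2,
    )
)
print(f"\nwrote {OUT / 'design.json'}")
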