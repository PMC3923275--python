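"""Quantifying one simulated ¹⁸O/¹⁶O pair at a known 5:1 mixing ratio.

Simulates the merged MS1 cluster of the invertase glycopeptide FATN*TTLTK
mixed heavy:light = 5:1 with 97% reagent purity, then runs the full
quantitation chain: envelope extraction, natural-overlap stripping,
purity inversion, and the closed-form and grouped ratios.
"""

from o18quant import (
    LabelingModel,
    extract_envelope,
    light_ion,
    purity_correct,
    ratio_formula1,
    ratio_formula3,
    simulate_pair,
    strip_species,
)
from o18quant.quant import envelope_ratios_for

ion = light_ion("FATNTTLTK", charge=2)
model = LabelingModel(ratio=5.0, purity=0.97)
spectra, truth = simulate_pair(ion, model, noise_cv=0.0, n_scans=5, seed=11)

r = envelope_ratios_for(ion)
env = extract_envelope(spectra, ion, rt_s=600.0)
print("extracted channels  I0..I6 :", [f"{v:.1f}" for v in env.even])

species = strip_species(env, r)
print("after stripping     S0..S6 :", [f"{v:.1f}" for v in species.s])
species = purity_correct(species, 0.97)
print("after purity invert S0..S6 :", [f"{v:.1f}" for v in species.s])

f1 = ratio_formula1(env, r)
f3 = ratio_formula3(species)
print(f"\nclosed-form ratio (light/heavy): {f1.value:.6f}   -> expect 0.2")
print(f"grouped ratio     (heavy/light): {f3.value:.6f}   -> expect 5.0")
print("\nThe grouped (GroupA+GroupB)/GroupC form recovers the planted 5:1 mix"
      "\nexactly once natural overlap and the 3% reagent impurity are removed.")
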