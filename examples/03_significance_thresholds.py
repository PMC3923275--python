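"""Three-sigma significance bands from replicate calibration SDs.

Derives the peptide- and protein-level change thresholds from the published
replicate SDs of a 1:1 standard mixture (seven repeated analyses) and
classifies a few example ratios.
"""

from o18quant.reference import MAX_SD_PEPTIDE, MAX_SD_PROTEIN, REPLICATE_SD
from o18quant.stats import classify_change, thresholds_from_sd

print("replicate SDs of the 1:1 standard mixture:")
for entity, sd in REPLICATE_SD.items():
    print(f"  {entity:<28} SD = {sd:.3f}")

for level, sd in (("peptide", MAX_SD_PEPTIDE), ("protein", MAX_SD_PROTEIN)):
    t = thresholds_from_sd(sd, level)
    print(f"\n{level} level (max SD {sd}):")
    print(f"  significant outside  [{t.lower_significant:.2f}, {t.upper_significant:.2f}]")
    print(f"  minor change within  [{t.lower_minor_high:.2f}, {t.upper_minor_low:.2f}] complement")

t = thresholds_from_sd(MAX_SD_PROTEIN, "protein")
print("\nexample protein-level calls:")
for ratio in (1.70, 1.30, 1.00, 0.70, 0.55):
    call = classify_change(ratio, t)
    print(f"  ratio {ratio:.2f} -> {call.classification}")
print("\nA ratio beyond 1 ± 3·SD of the 1:1 calibration is a significant"
      "\nchange (~99% confidence); between 1 and 3 SD it is a minor change.")
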