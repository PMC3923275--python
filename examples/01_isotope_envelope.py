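"""Masses and envelopes of a labeled glycopeptide pair.

Builds the clusterin glycopeptide LAN*LTQGEDQYYLR in its light (¹⁶O) and
heavy (three ¹⁸O labels) forms, and prints the precursor m/z values, the
6-Da pair shift, and the theoretical isotope envelope that the overlap
correction uses.
"""

from o18quant import ion_mz, isotope_distribution, label_mass_shift, peptide_composition
from o18quant.masscalc import PeptideIon, parse_modifications
from o18quant.reference import CLUSTERIN_PAIR

light = PeptideIon("LANLTQGEDQYYLR", parse_modifications("3:Deamidation"), 2, (3,))
heavy = PeptideIon(
    "LANLTQGEDQYYLR", parse_modifications("3:Deamidation18O;cterm:2x18O"), 2, (3,)
)

print(f"light  [M+2H]2+ : {ion_mz(light):.5f} Th  (published {CLUSTERIN_PAIR['mz_light']})")
print(f"heavy  [M+2H]2+ : {ion_mz(heavy):.5f} Th  (published {CLUSTERIN_PAIR['mz_heavy']})")
print(f"pair shift      : {label_mass_shift(1):.5f} Da (nominal 6 Da; /2 charges = "
      f"{label_mass_shift(1) / 2:.5f} Th)")

dist = isotope_distribution(peptide_composition(light))
print("\ntheoretical envelope (relative to M0):")
for k in (0, 1, 2, 3, 4, 5, 6):
    print(f"  M{k}: {dist.ratio(k):.4f}")
print("\nThe even-offset ratios M2/M0, M4/M0, M6/M0 are the coefficients that"
      "\nremove natural-isotope overlap from the +2/+4/+6 channels of a pair.")
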