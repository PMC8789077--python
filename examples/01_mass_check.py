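"""Verify conjugate identity from molecular formulas and MALDI adducts.

Computes average molecular weights for the published peptide and
conjugate formulas and the m/z of their observed adduct ions.  The
rounded values should match the numbers printed on the MALDI
characterisation sheets to within 1 Da.
"""

from rnacat import adduct_mz, average_mass
from rnacat.datasets import CONJUGATE_ADDUCTS, CONJUGATE_FORMULAS

for name, formula in CONJUGATE_FORMULAS.items():
    m = average_mass(formula)
    print(f"{name:18s} {formula:24s} MW = {m:9.2f} Da  (rounded {round(m)})")

print()
for name, adduct, printed in CONJUGATE_ADDUCTS:
    mz = adduct_mz(average_mass(CONJUGATE_FORMULAS[name]), adduct)
    print(f"{name:18s} [{adduct}]+  m/z = {round(mz)}  (printed {printed})")

print("\nEach rounded MW/adduct m/z identifies the synthesised species; a"
      "\nmismatch beyond +/-1 Da would indicate a failed or wrong conjugation.")
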