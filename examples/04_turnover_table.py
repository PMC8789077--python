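"""Turnover numbers from the published multiple-turnover quantification.

Each conjugate (0.5 nmol = 5 uM in 100 ul) was incubated 96 h with
2-30 fold excess of the FRET reporter substrate; the table records the
cleaved amount in nmol.  Dividing by the conjugate amount gives
substrate molecules cleaved per conjugate molecule - values above 1
demonstrate genuine "bind, cleave and leave" catalysis.
"""

from rnacat import turnover_per_conjugate
from rnacat.datasets import TURNOVER_CONJUGATE_NMOL, turnover_table

table = turnover_table()
table["turnover"] = [
    turnover_per_conjugate(x, TURNOVER_CONJUGATE_NMOL).rounded
    for x in table.cleaved_nmol
]
print(table.pivot(index="substrate_uM", columns="conjugate",
                  values="turnover"))
print(f"\nconjugate amount: {TURNOVER_CONJUGATE_NMOL} nmol per reaction")
print("Turnover rises with substrate excess up to 10-20x and then falls"
      "\nagain at 20-30x - the parabolic signature of catalyst"
      "\ninactivation at high substrate load.")
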