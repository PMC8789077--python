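"""Small published reference data used by examples and acceptance checks.

The raw kinetic data of the study this package reimplements were never
deposited; what is public are the printed characterisation values
(molecular formulas and MALDI masses), the conjugate and target
sequences, the gel-shift association constants, and the quantification
table of the multiple-turnover experiment (cleaved amount in nmol per
condition).  Those printed values are inputs to the analysis and ship
here as plain data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "YEAST_TRNA_PHE",
    "FQ_RNA_TARGET",
    "RECOGNITION_MOTIF",
    "CONJUGATE_FORMULAS",
    "CONJUGATE_ADDUCTS",
    "BINDING_CONSTANTS",
    "turnover_table",
    "TURNOVER_CONJUGATE_NMOL",
]

#: Yeast tRNA-Phe (76 nt, modified bases written as parent bases).
YEAST_TRNA_PHE = (
    "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCACCA"
)

#: Linear 31-mer FRET reporter target: DNA backbone except the central
#: 5-nt ribonucleotide bulge-loop region (CACAG), matching the tRNA-Phe
#: 3'-acceptor-stem / TPsiC-arm / variable-loop region.  Written 5'->3'
#: in DNA letters; the ribo region is positions 14-18 (0-based 13..17).
FQ_RNA_TARGET = "GTCCTGTGTTCGATCCACAGAATTCGCACCA"

#: The 26-nt antisense recognition motif (DNA, 5'->3') shared by the
#: bulge-loop conjugates, with the internal abasic attachment
#: nucleotides omitted.
RECOGNITION_MOTIF = "TGGTGCGAATTGATCGAACACAGGAC"

#: Printed Hill formulas (characterisation sheets).
CONJUGATE_FORMULAS = {
    "peptide_LR3G": "C40H76N16O9",
    "bis_conjugate": "C385H563N151O187P28",   # BC5-L-aa/bb/ab/ba share one formula
    "triple_conjugate": "C409H609N156O194P29",
}

#: Printed MALDI adduct assignments: (formula key, adduct, printed m/z).
CONJUGATE_ADDUCTS = [
    ("peptide_LR3G", "M+H", 926),
    ("bis_conjugate", "M+Na", 11189),
    ("bis_conjugate", "M+Na+H", 11190),
    ("triple_conjugate", "M+Na", 11736),
]

#: Gel-shift association constants (M^-1) with reported uncertainties.
BINDING_CONSTANTS = {
    "BC5-L-bb": (1.1e6, 0.9e6),
    "BC5-L-aa": (3.5e6, 0.8e6),
    "BC5-L-ab": (4.3e6, 2.2e6),
    "BC5-L-ba": (6.2e6, 2.3e6),
    "BC5-L-bbb": (0.5e6, 0.1e6),
}

#: Conjugate amount in the multiple-turnover design: 5 uM in 100 ul.
TURNOVER_CONJUGATE_NMOL = 0.5

_TURNOVER_ROWS = [
    # substrate_uM, substrate_nmol, cleaved nmol per conjugate
    (10, 1.0, {"BC5-L-bb": 1.0, "BC5-L-b": 0.6, "BC5-a": 0.6}),
    (25, 2.5, {"BC5-L-bb": 2.0, "BC5-L-b": 1.8, "BC5-a": 1.5}),
    (50, 5.0, {"BC5-L-bb": 3.3, "BC5-L-b": 2.5, "BC5-a": 2.9}),
    (100, 10.0, {"BC5-L-bb": 2.7, "BC5-L-b": 2.8, "BC5-a": 3.2}),
    (150, 15.0, {"BC5-L-bb": 2.8, "BC5-L-b": 1.6, "BC5-a": 1.8}),
]


def turnover_table() -> pd.DataFrame:
    """Published multiple-turnover quantification, long format.

    Columns: conjugate, substrate_uM, substrate_nmol, cleaved_nmol.
    The derived turnover numbers (molecules cleaved per conjugate) are
    *not* included - they are recomputed by
    :func:`rnacat.quantify.turnover_per_conjugate`.
    """
    rows = []
    for s_uM, s_nmol, cleaved in _TURNOVER_ROWS:
        for conj, nmol in cleaved.items():
            rows.append({
                "conjugate": conj,
                "substrate_uM": s_uM,
                "substrate_nmol": s_nmol,
                "cleaved_nmol": nmol,
            })
    return pd.DataFrame(rows)
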