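"""Molecular-formula mass arithmetic and MALDI adduct m/z.

Conjugate identity QC works from Hill-notation molecular formulas
(e.g. ``"C385H563N151O187P28"``) and compares the computed average
molecular weight, rounded to the nearest dalton, with the value printed
on a MALDI-TOF characterisation sheet.  Average (not monoisotopic)
masses are the right comparison for broad MALDI peaks of multi-kDa
oligonucleotide conjugates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "average_mass",
    "adduct_mz",
    "ATOMIC_WEIGHTS",
    "ADDUCT_MASSES",
    "FormulaError",
]

# IUPAC standard average atomic weights, 4 decimal places.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.0080,
    "B": 10.8110,
    "C": 12.0110,
    "N": 14.0070,
    "O": 15.9990,
    "F": 18.9984,
    "Na": 22.9898,
    "Mg": 24.3050,
    "Si": 28.0850,
    "P": 30.9738,
    "S": 32.0600,
    "Cl": 35.4500,
    "K": 39.0983,
    "Ca": 40.0780,
    "Mn": 54.9380,
    "Fe": 55.8450,
    "Co": 58.9332,
    "Ni": 58.6934,
    "Cu": 63.5460,
    "Zn": 65.3800,
    "Se": 78.9710,
    "Br": 79.9040,
    "I": 126.9045,
}

# Mass added by each singly-charged positive adduct (Da).  The electron
# mass is negligible at the +/-1 Da reporting precision used here.
ADDUCT_MASSES: Mapping[str, float] = {
    "M+H": 1.008,
    "M+Na": 22.990,
    "M+Na+H": 22.990 + 1.008,
}


class FormulaError(ValueError):
    """Raised for malformed Hill strings or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition as a mapping ``symbol -> count``.

    Counts over repeated element tokens are summed, so ``"CH3CH3"``
    and ``"C2H6"`` denote the same formula.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        for sym, n in counts.items():
            if sym not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"bad count for {sym}: {n!r}")
        counts = {s: n for s, n in counts.items() if n}  # canonical: no zeros
        if not counts:
            raise FormulaError("formula has no atoms")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, hill_string: str) -> "MolecularFormula":
        return parse_formula(hill_string)

    @property
    def mass(self) -> float:
        """Average molecular mass in Da."""
        return sum(ATOMIC_WEIGHTS[s] * n for s, n in self.element_counts.items())

    def hill(self) -> str:
        """Canonical Hill notation: C, H first, then alphabetical."""
        counts = self.element_counts
        order = [s for s in ("C", "H") if counts.get(s)]
        order += sorted(s for s in counts if s not in ("C", "H") and counts[s])
        return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in order)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(hill_string: str) -> MolecularFormula:
    """Parse a Hill-notation formula string.

    Repeated element tokens are accumulated.  Raises
    :class:`FormulaError` on unknown symbols or malformed input.
    """
    s = hill_string.strip()
    if not s:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula at position {pos}: {s!r}")
        sym, digits = m.groups()
        if sym not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol: {sym!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def average_mass(formula: MolecularFormula | str) -> float:
    """Average molecular mass (Da) from IUPAC standard atomic weights.

    Round the result to the nearest integer to compare with a printed
    MW; printed values are matched to +/-1 Da.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.mass


def adduct_mz(mass: float, adduct: str) -> float:
    """m/z of a singly-charged adduct ion.

    Parameters
    ----------
    mass
        Neutral average mass in Da (must be positive).
    adduct
        One of ``"M+H"``, ``"M+Na"``, ``"M+Na+H"``.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    try:
        delta = ADDUCT_MASSES[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_MASSES)}"
        ) from None
    return mass + delta
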