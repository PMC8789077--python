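"""Sliding-window off-target duplex-stability screen.

Antisense recognition motifs must not form stable hybrids anywhere on
the target RNA outside the intended site.  The screen slides a window
along the target with a 1-nt step and scores the DNA-probe / RNA-window
hybrid with a published nearest-neighbor (NN) parameter set for
RNA/DNA hybrids (Sugimoto et al. 1995, as distributed with Biopython).
Parameters are at the 1 M NaCl reference state and no salt correction
is applied; the screen output ranks windows comparatively rather than
predicting absolute melting behaviour.

Scoring convention: the probe (DNA, 5'->3') is aligned antiparallel to
the window (5'->3'), pairing probe position ``i`` with window position
``n-1-i``.  Only Watson-Crick matched stacks (both neighbouring pairs
complementary, U and T equivalent) contribute NN terms; mismatched
steps contribute nothing, so a window with zero complementarity scores
only the (destabilising) initiation term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = ["DuplexWindow", "scan_offtarget", "hybrid_thermo", "SequenceError"]

T_KELVIN_37C = 310.15
_R_GAS = 1.987  # cal/(mol K)

_ALPHABET = set("ACGTU")
_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C"}

#: NN table: key "XY/WZ" = probe dinucleotide (DNA 5'->3') over its
#: complement; value (dH kcal/mol, dS cal/(mol K)).
HYBRID_NN_TABLE = dict(_mt.R_DNA_NN1)


class SequenceError(ValueError):
    """Raised for non-ACGUT characters or impossible window sizes."""


@dataclass(frozen=True)
class DuplexWindow:
    """One scored probe/window hybrid.

    ``delta_g`` is at 37 C in kcal/mol; ``delta_h`` kcal/mol; ``delta_s``
    cal/(mol K); ``tm`` the two-state melting temperature in Celsius
    (NaN when the hybrid has no net favourable enthalpy).
    """

    start: int
    window_seq: str
    delta_g: float
    delta_h: float
    delta_s: float
    tm: float
    stable: bool


def _clean(seq: str, what: str) -> str:
    s = seq.strip().upper().replace(" ", "")
    bad = set(s) - _ALPHABET
    if bad:
        raise SequenceError(f"{what} contains non-ACGUT characters: {sorted(bad)}")
    if not s:
        raise SequenceError(f"{what} is empty")
    return s


def _dna(nt: str) -> str:
    return "T" if nt == "U" else nt


def hybrid_thermo(
    probe: str,
    window: str,
    strand_conc_uM: float = 1.0,
) -> tuple[float, float, float, float]:
    """NN thermodynamics of a probe/window hybrid.

    Returns ``(delta_h, delta_s, delta_g37, tm_celsius)``.  The two-state
    Tm uses total strand concentration ``strand_conc_uM`` (non-self-
    complementary duplex, CT/4 convention).
    """
    p = _clean(probe, "probe")
    w = _clean(window, "window")
    n = len(w)
    L = min(len(p), n)
    # pairing mask: probe[i] against window[n-1-i]
    match = [
        _COMPLEMENT[_dna(p[i])] == _dna(w[n - 1 - i]) for i in range(L)
    ]
    dh, ds = HYBRID_NN_TABLE["init"]
    for i in range(L - 1):
        if match[i] and match[i + 1]:
            step = _dna(p[i]) + _dna(p[i + 1])
            comp = _COMPLEMENT[step[0]] + _COMPLEMENT[step[1]]
            h, s = HYBRID_NN_TABLE[f"{step}/{comp}"]
            dh += h
            ds += s
    dg37 = dh - T_KELVIN_37C * ds / 1000.0
    ct = strand_conc_uM * 1e-6
    denom = ds + _R_GAS * math.log(ct / 4.0)
    if dh < 0 and denom < 0:
        tm = 1000.0 * dh / denom - 273.15
    else:
        tm = math.nan
    return dh, ds, dg37, tm


def scan_offtarget(
    probe: str,
    target: str,
    window: int = 26,
    step: int = 1,
    strand_conc_uM: float = 1.0,
    tm_threshold_C: float = 37.0,
    sort_by_dg: bool = False,
) -> list[DuplexWindow]:
    """Score the probe against every length-``window`` segment of the target.

    Emits exactly ``floor((len(target) - window)/step) + 1`` windows.  A
    window is flagged ``stable`` when its two-state Tm reaches
    ``tm_threshold_C`` (windows with NaN Tm are never stable).
    """
    p = _clean(probe, "probe")
    t = _clean(target, "target")
    if window < 2:
        raise SequenceError("window must be at least 2 nt")
    if window > len(t):
        raise SequenceError(
            f"window ({window}) exceeds target length ({len(t)})"
        )
    if step < 1:
        raise SequenceError("step must be >= 1")
    out: list[DuplexWindow] = []
    for start in range(0, len(t) - window + 1, step):
        wseq = t[start : start + window]
        dh, ds, dg, tm = hybrid_thermo(p, wseq, strand_conc_uM)
        stable = (not math.isnan(tm)) and tm >= tm_threshold_C
        out.append(DuplexWindow(start, wseq, dg, dh, ds, tm, stable))
    if sort_by_dg:
        out.sort(key=lambda w: w.delta_g)
    return out
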