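"""Reduction of raw cleavage readouts to extents, products and turnover.

Two readouts feed the kinetic analysis:

* a FRET de-quenching fluorescence time course, normalised between the
  matched untreated-target background and an RNase-A fully-cleaved
  reference (100% cleavage);
* gel band-intensity tables from density scans, with each band assigned
  to the intact target, a bulge-loop cleavage site, or an ex-bulge
  (nearby-fold) site.

From either, the module derives percent cleaved, product concentration,
amounts in nmol, and substrate molecules cleaved per conjugate molecule
(the turnover number of the "bind, cleave and leave" cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReactionConditions",
    "FluorescenceSeries",
    "ExtentResult",
    "GelBand",
    "GelLaneTable",
    "CleavageProfile",
    "PathwayResult",
    "Turnover",
    "extent_of_cleavage",
    "product_concentration",
    "amount_from_concentration",
    "turnover_per_conjugate",
    "quantify_gel",
    "pathway_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactionConditions:
    """Totals for one multiple-turnover incubation."""

    substrate_uM: float
    conjugate_uM: float
    volume_ul: float = 100.0

    def __post_init__(self) -> None:
        if self.substrate_uM < 0 or self.conjugate_uM <= 0 or self.volume_ul <= 0:
            raise ValueError("concentrations/volume out of range")

    @property
    def excess_ratio(self) -> float:
        """Substrate:conjugate molar ratio."""
        return self.substrate_uM / self.conjugate_uM

    @property
    def conjugate_nmol(self) -> float:
        return amount_from_concentration(self.conjugate_uM, self.volume_ul)

    @property
    def substrate_nmol(self) -> float:
        return amount_from_concentration(self.substrate_uM, self.volume_ul)


@dataclass(frozen=True)
class FluorescenceSeries:
    """Raw plate-reader time course for one reaction condition.

    ``background`` is the matched untreated-target fluorescence per time
    point; ``full_cleavage_ref`` the fluorescence of the RNase-A
    fully-cleaved control of the same substrate.
    """

    times_h: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    full_cleavage_ref: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        r = np.asarray(self.raw, dtype=float)
        b = np.asarray(self.background, dtype=float)
        if t.ndim != 1 or t.size < 1 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if r.shape != t.shape or b.shape != t.shape:
            raise ValueError("raw/background must match the time grid")
        if self.full_cleavage_ref <= float(np.mean(b)):
            raise ValueError("full-cleavage reference must exceed mean background")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "raw", r)
        object.__setattr__(self, "background", b)


class ExtentResult(NamedTuple):
    percent: np.ndarray
    clipped: bool


def extent_of_cleavage(f: FluorescenceSeries) -> ExtentResult:
    """Percent cleaved per time point.

    ``100 * (raw - background) / (full_cleavage_ref - background)``,
    clipped to [0, 100]; clipping is logged and flagged, never silent.
    """
    denom = f.full_cleavage_ref - f.background
    if np.any(denom <= 0):
        raise ValueError("full-cleavage reference does not exceed background")
    pct = 100.0 * (f.raw - f.background) / denom
    clipped = bool(np.any(pct < 0) or np.any(pct > 100))
    if clipped:
        logger.warning(
            "extent of cleavage clipped to [0, 100] (raw range %.3g..%.3g%%)",
            float(np.min(pct)), float(np.max(pct)),
        )
        pct = np.clip(pct, 0.0, 100.0)
    return ExtentResult(pct, clipped)


def product_concentration(extent_pct, s0_uM: float):
    """Product concentration [P] = extent/100 * [S]0, in uM."""
    extent = np.asarray(extent_pct, dtype=float)
    if np.any(extent < 0) or np.any(extent > 100):
        raise ValueError("extent must be within [0, 100] percent")
    out = extent / 100.0 * s0_uM
    return float(out) if out.ndim == 0 else out


def amount_from_concentration(conc_uM: float, volume_ul: float) -> float:
    """nmol = uM * ul / 1000."""
    if conc_uM < 0 or volume_ul < 0:
        raise ValueError("inputs must be non-negative")
    return conc_uM * volume_ul / 1000.0


class Turnover(NamedTuple):
    """Substrate molecules cleaved per conjugate molecule."""

    value: float
    rounded: float  # to 1 decimal place, as conventionally reported


def turnover_per_conjugate(cleaved_nmol: float, conjugate_nmol: float) -> Turnover:
    if conjugate_nmol <= 0:
        raise ValueError("conjugate amount must be positive")
    if cleaved_nmol < 0:
        raise ValueError("cleaved amount must be non-negative")
    v = cleaved_nmol / conjugate_nmol
    return Turnover(v, round(v, 1))


# --------------------------------------------------------------------------
# Gel quantification


@dataclass(frozen=True)
class GelBand:
    """Band identity: 'intact', 'bulge' or 'exbulge', with a site label
    for product bands (e.g. the phosphodiester position it maps to)."""

    kind: str
    site: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intact", "bulge", "exbulge"):
            raise ValueError(f"unknown band class {self.kind!r}")
        if self.kind != "intact" and not self.site:
            raise ValueError("product bands need a site label")


@dataclass(frozen=True)
class GelLaneTable:
    """Per-lane band intensities over time.

    ``bands`` maps band_id -> intensity array over ``times_h``;
    ``band_map`` maps band_id -> :class:`GelBand`.  Exactly one band
    must be classified intact.
    """

    times_h: np.ndarray
    bands: Mapping[str, np.ndarray]
    band_map: Mapping[str, GelBand]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        object.__setattr__(self, "times_h", t)
        bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}
        for bid, v in bands.items():
            if v.shape != t.shape:
                raise ValueError(f"band {bid!r} does not match the time grid")
            if np.any(v < 0):
                raise ValueError(f"band {bid!r} has negative intensity")
            if bid not in self.band_map:
                raise ValueError(f"band {bid!r} missing from band map")
        n_intact = sum(1 for b in self.band_map.values() if b.kind == "intact")
        if n_intact != 1:
            raise ValueError("exactly one intact band is required")
        object.__setattr__(self, "bands", bands)


@dataclass(frozen=True)
class CleavageProfile:
    """Total/bulge/per-site cleavage extents (%) over time."""

    times_h: np.ndarray
    total_pct: np.ndarray
    bulge_pct: np.ndarray
    exbulge_pct: np.ndarray
    per_site_pct: Mapping[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_h": self.times_h,
            "total_pct": self.total_pct,
            "bulge_pct": self.bulge_pct,
            "exbulge_pct": self.exbulge_pct,
        }
        for site, v in self.per_site_pct.items():
            data[f"site_{site}_pct"] = v
        return pd.DataFrame(data)


def quantify_gel(g: GelLaneTable) -> CleavageProfile:
    """Cleavage extents from band intensities.

    Lane-internal normalisation: the denominator is the total assigned
    signal of the lane (intact + all product bands), which makes the
    result robust to loading variation.  ``total = 100 * (1 - intact /
    lane_total)``; each product band contributes its intensity fraction
    to its site; bulge percent is the sum over bulge-site bands.
    """
    intact_id = next(k for k, b in g.band_map.items() if b.kind == "intact")
    lane_total = np.sum([v for v in g.bands.values()], axis=0)
    if np.any(lane_total <= 0):
        raise ValueError("lane with zero total signal")
    total = 100.0 * (1.0 - g.bands[intact_id] / lane_total)
    per_site: dict[str, np.ndarray] = {}
    bulge = np.zeros_like(total)
    exbulge = np.zeros_like(total)
    for bid, band in g.band_map.items():
        if band.kind == "intact":
            continue
        frac = 100.0 * g.bands[bid] / lane_total
        per_site[band.site] = per_site.get(band.site, 0.0) + frac
        if band.kind == "bulge":
            bulge = bulge + frac
        else:
            exbulge = exbulge + frac
    return CleavageProfile(g.times_h, total, bulge, exbulge, per_site)


class PathwayResult(NamedTuple):
    """Bulge-vs-exbulge trajectory and the takeover point, if any.

    ``takeover_exbulge_pct`` is the (interpolated) ex-bulge extent at
    which the bulge cleavage rate first matches or exceeds the ex-bulge
    rate; ``occurred`` is False when the rates never cross.
    """

    exbulge_pct: np.ndarray
    bulge_pct: np.ndarray
    takeover_exbulge_pct: float
    occurred: bool


def pathway_curve(p: CleavageProfile) -> PathwayResult:
    """Order-of-events analysis of bulge vs ex-bulge cleavage.

    Finite-difference rates are located at interval midpoints; the
    takeover is the first interval where d(bulge)/dt - d(exbulge)/dt
    >= 0 (ties go to the earlier index).  The crossing time is found by
    linear interpolation of the rate difference between midpoints, and
    the reported value is the ex-bulge extent interpolated at that
    time; a crossing already in the first interval reports the first
    point's ex-bulge extent.
    """
    if p.times_h.size < 3:
        raise ValueError("need at least 3 time points")
    dt = np.diff(p.times_h)
    mids = p.times_h[:-1] + dt / 2.0
    rb = np.diff(p.bulge_pct) / dt
    re = np.diff(p.exbulge_pct) / dt
    diff = rb - re
    if np.all(p.bulge_pct == 0) or not np.any(diff >= 0):
        return PathwayResult(p.exbulge_pct, p.bulge_pct, np.nan, False)
    i = int(np.argmax(diff >= 0))  # first interval with crossing
    if i == 0:
        x = float(p.exbulge_pct[0])
    else:
        f = diff[i - 1] / (diff[i - 1] - diff[i])
        t_cross = mids[i - 1] + f * (mids[i] - mids[i - 1])
        x = float(np.interp(t_cross, p.times_h, p.exbulge_pct))
    return PathwayResult(p.exbulge_pct, p.bulge_pct, x, True)
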