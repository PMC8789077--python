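"""Synthetic raw-data generation with known ground truth.

Every input the analysis pipeline consumes can be generated here from
the forward model, so that each pipeline stage has a fixture whose
truth is known exactly:

* :func:`generate_assay` - plate-reader fluorescence time courses from
  :func:`rnacat.model.simulate_reaction`, by inverting the assay
  normalisation (raw = background + (P/S0) * (ref - background)) and
  adding plate-reader-like multiplicative noise;
* :func:`generate_gel_fixture` - gel lane band-intensity tables that
  invert through :func:`rnacat.quantify.quantify_gel`;
* :func:`generate_binding_fixture` - gel-shift titrations from the
  exact 1:1 mass-action isotherm.

All randomness flows from the single seed recorded in the
:class:`NoiseSpec`; regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binding import BindingMeasurement, bound_fraction
from .model import EquilibriumParams, KineticParams, simulate_reaction
from .presets import STANDARD_TIMES_H, standard_conditions
from .progress import ProgressCurve
from .quantify import (
    FluorescenceSeries,
    GelBand,
    GelLaneTable,
    ReactionConditions,
    extent_of_cleavage,
    product_concentration,
)

__all__ = [
    "NoiseSpec",
    "AssayFixture",
    "generate_assay",
    "generate_gel_fixture",
    "generate_binding_fixture",
    "verify_assay_fixture",
]

#: Untreated-target background fluorescence (arbitrary units).
DEFAULT_BACKGROUND = 50.0
#: Fluorescence gain per uM of fully-cleaved substrate.
DEFAULT_GAIN = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian noise with an additive floor.

    ``multiplicative_cv`` is the coefficient of variation applied to
    each raw reading; ``additive_floor`` the smallest reportable
    fluorescence (readings never fall below it, nor below zero).
    """

    multiplicative_cv: float = 0.05
    additive_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class AssayFixture:
    """Generated fluorescence series with their ground truth."""

    conditions: tuple[ReactionConditions, ...]
    series: tuple[FluorescenceSeries, ...]
    true_product_uM: tuple[np.ndarray, ...]
    truth: Mapping[str, object]

    def progress_curves(self) -> list[ProgressCurve]:
        """Reduce the (noisy) series back to product curves."""
        out = []
        for cond, fs in zip(self.conditions, self.series):
            pct = extent_of_cleavage(fs).percent
            out.append(ProgressCurve(
                fs.times_h, product_concentration(pct, cond.substrate_uM),
                cond.substrate_uM,
                condition_id=f"excess_{cond.excess_ratio:g}",
            ))
        return out


def generate_assay(
    eq: EquilibriumParams,
    kin: KineticParams,
    conditions: Sequence[ReactionConditions] | None = None,
    t_grid: Sequence[float] = STANDARD_TIMES_H,
    noise: NoiseSpec = NoiseSpec(multiplicative_cv=0.0),
    background: float = DEFAULT_BACKGROUND,
    gain: float = DEFAULT_GAIN,
    nu: int = 2,
    max_step: float = 0.1,
) -> AssayFixture:
    """Simulate the standard multiple-turnover assay design.

    Defaults mirror the study design: 5 uM conjugate with substrate at
    2-30 fold excess in 100 ul, sampled at 0/24/48/72/96 h.  The
    full-cleavage reference scales with substrate (ref = background +
    gain * S0), and noise is applied multiplicatively to the raw
    readings only - matched background and reference controls are
    taken as noiseless.
    """
    if conditions is None:
        conditions = standard_conditions()
    rng = np.random.default_rng(noise.seed)
    t = np.asarray(t_grid, dtype=float)
    series, truths = [], []
    for cond in conditions:
        states = simulate_reaction(eq, kin, cond, t, max_step=max_step, nu=nu)
        p = np.array([st.P for st in states])
        truths.append(p)
        ref = background + gain * cond.substrate_uM
        raw = background + (p / cond.substrate_uM) * (ref - background)
        if noise.multiplicative_cv > 0:
            raw = raw * (1.0 + noise.multiplicative_cv * rng.standard_normal(t.size))
        raw = np.maximum(raw, max(noise.additive_floor, 0.0))
        series.append(FluorescenceSeries(
            times_h=t, raw=raw,
            background=np.full(t.size, background),
            full_cleavage_ref=ref,
        ))
    truth = {
        "equilibrium": {k: v for k, v in asdict(eq).items()},
        "kinetic": asdict(kin),
        "noise": asdict(noise),
        "nu": nu,
        "background": background,
        "gain": gain,
        "t_grid": list(map(float, t)),
        "conditions": [asdict(c) for c in conditions],
    }
    return AssayFixture(tuple(conditions), tuple(series),
                        tuple(truths), truth)


def verify_assay_fixture(fix: AssayFixture) -> float:
    """Max |recovered - true| product concentration (uM) over the fixture.

    Recovery runs the real analysis stage (normalisation then product
    conversion); at zero noise the error is at numerical precision.
    """
    err = 0.0
    for curve, true_p in zip(fix.progress_curves(), fix.true_product_uM):
        err = max(err, float(np.max(np.abs(curve.product_uM - true_p))))
    return err


def generate_gel_fixture(
    times_h: Sequence[float],
    site_profiles: Mapping[str, tuple[str, Sequence[float]]],
    noise: NoiseSpec = NoiseSpec(multiplicative_cv=0.0),
    lane_scale: float = 1000.0,
) -> GelLaneTable:
    """Gel lane table from per-site cleavage percentages.

    ``site_profiles`` maps site label -> (band class, percent-over-time)
    with class 'bulge' or 'exbulge'.  Site percentages must lie in
    [0, 100] and sum to <= 100 at every lane; the intact band carries
    the remainder, so :func:`rnacat.quantify.quantify_gel` inverts the
    fixture exactly at zero noise.
    """
    t = np.asarray(times_h, dtype=float)
    rng = np.random.default_rng(noise.seed)
    profiles = {k: (kind, np.asarray(v, dtype=float))
                for k, (kind, v) in site_profiles.items()}
    total = np.sum([v for _, v in profiles.values()], axis=0)
    if np.any(total > 100.0 + 1e-9):
        raise ValueError("site percentages exceed 100% in some lane")
    for _, v in profiles.values():
        if np.any(v < 0) or np.any(np.diff(v) < -1e-9):
            raise ValueError("site cleavage must be non-negative and non-decreasing")
    bands = {"intact": lane_scale * (100.0 - total) / 100.0}
    band_map = {"intact": GelBand("intact")}
    for site, (kind, v) in profiles.items():
        bid = f"{kind}_{site}"
        bands[bid] = lane_scale * v / 100.0
        band_map[bid] = GelBand(kind, site)
    if noise.multiplicative_cv > 0:
        bands = {
            k: np.maximum(
                v * (1.0 + noise.multiplicative_cv * rng.standard_normal(t.size)),
                0.0,
            )
            for k, v in bands.items()
        }
    return GelLaneTable(t, bands, band_map)


def generate_binding_fixture(
    ka_M: float,
    trna_uM: float,
    conjugate_grid_uM: Sequence[float],
    noise: NoiseSpec = NoiseSpec(multiplicative_cv=0.0),
) -> list[BindingMeasurement]:
    """Gel-shift titration from the exact 1:1 isotherm.

    Noise is multiplicative on the bound fraction, truncated to
    [0, 1) so every generated point stays in the closed form's domain.
    """
    if ka_M < 0:
        raise ValueError("Ka must be non-negative")
    rng = np.random.default_rng(noise.seed)
    out = []
    for c in conjugate_grid_uM:
        a = bound_fraction(ka_M, c, trna_uM)
        if noise.multiplicative_cv > 0:
            a *= 1.0 + noise.multiplicative_cv * rng.standard_normal()
        a = float(np.clip(a, 0.0, 1.0 - 1e-9))
        out.append(BindingMeasurement(c, trna_uM, a))
    return out
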