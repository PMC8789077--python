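"""Plain-text I/O: the CSV/JSON dialects shared by all pipeline stages.

Every intermediate artifact is an inspectable CSV or JSON file; no
binary formats.  Readers accept exactly what the matching writers (and
the synthetic-data generators) produce.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import BindingMeasurement
from .model import EquilibriumParams, KineticParams
from .progress import ProgressCurve
from .quantify import (
    FluorescenceSeries,
    GelBand,
    GelLaneTable,
    ReactionConditions,
)
from .synth import AssayFixture

__all__ = [
    "read_sequence",
    "read_fluorescence_csv",
    "write_fluorescence_csv",
    "read_gel_tables",
    "write_gel_tables",
    "read_binding_csv",
    "write_binding_csv",
    "read_progress_csv",
    "write_progress_csv",
    "read_conditions_csv",
    "write_conditions_csv",
    "load_params",
    "dump_params",
    "write_assay_fixture",
    "read_assay_fixture",
    "file_sha256",
]


def read_sequence(source: str | Path) -> str:
    """A nucleotide sequence from a FASTA file or a plain string.

    A path to an existing file is parsed as FASTA (first record);
    anything else is treated as the sequence itself.
    """
    p = Path(str(source))
    if p.exists() and p.is_file():
        rec = next(SeqIO.parse(str(p), "fasta"))
        return str(rec.seq)
    return str(source)


# -- fluorescence -----------------------------------------------------------

def write_fluorescence_csv(path: str | Path, fs: FluorescenceSeries) -> None:
    df = pd.DataFrame({
        "time_h": fs.times_h, "raw": fs.raw, "background": fs.background,
        "full_cleavage_ref": np.full(fs.times_h.size, fs.full_cleavage_ref),
    })
    df.to_csv(path, index=False)


def read_fluorescence_csv(
    path: str | Path, ref: float | None = None
) -> FluorescenceSeries:
    """Columns time_h, raw, background; the full-cleavage reference can
    come from a full_cleavage_ref column or the ``ref`` argument."""
    df = pd.read_csv(path)
    if ref is None:
        if "full_cleavage_ref" not in df.columns:
            raise ValueError(
                f"{path}: no full_cleavage_ref column and no --ref given"
            )
        ref = float(df["full_cleavage_ref"].iloc[0])
    return FluorescenceSeries(
        times_h=df["time_h"].to_numpy(float),
        raw=df["raw"].to_numpy(float),
        background=df["background"].to_numpy(float),
        full_cleavage_ref=ref,
    )


# -- gel --------------------------------------------------------------------

def write_gel_tables(
    lanes_path: str | Path, map_path: str | Path, g: GelLaneTable
) -> None:
    rows = [
        {"time_h": t, "band_id": bid, "intensity": g.bands[bid][i]}
        for i, t in enumerate(g.times_h)
        for bid in g.bands
    ]
    pd.DataFrame(rows).to_csv(lanes_path, index=False)
    pd.DataFrame([
        {"band_id": bid, "class": b.kind, "site_label": b.site or ""}
        for bid, b in g.band_map.items()
    ]).to_csv(map_path, index=False)


def read_gel_tables(lanes_path: str | Path, map_path: str | Path) -> GelLaneTable:
    """Long-format lane table (time_h, band_id, intensity) plus a band
    map (band_id, class, site_label)."""
    lanes = pd.read_csv(lanes_path)
    bmap = pd.read_csv(map_path, dtype={"band_id": str}, keep_default_na=False)
    times = np.sort(lanes["time_h"].unique())
    wide = lanes.pivot_table(index="time_h", columns="band_id",
                             values="intensity").reindex(times)
    bands = {str(b): wide[b].to_numpy(float) for b in wide.columns}
    band_map = {
        str(r.band_id): GelBand(r["class"], r.site_label or None)
        for _, r in bmap.iterrows()
    }
    return GelLaneTable(times, bands, band_map)


# -- binding ----------------------------------------------------------------

def write_binding_csv(path: str | Path,
                      points: Sequence[BindingMeasurement]) -> None:
    pd.DataFrame([
        {"conjugate_uM": m.conjugate_uM, "trna_uM": m.trna_uM,
         "fraction_bound": m.fraction_bound,
         **({"sd": m.sd} if m.sd is not None else {})}
        for m in points
    ]).to_csv(path, index=False)


def read_binding_csv(path: str | Path) -> list[BindingMeasurement]:
    df = pd.read_csv(path)
    return [
        BindingMeasurement(
            float(r.conjugate_uM), float(r.trna_uM), float(r.fraction_bound),
            sd=float(r.sd) if "sd" in df.columns and pd.notna(r.sd) else None,
        )
        for _, r in df.iterrows()
    ]


# -- progress curves --------------------------------------------------------

def write_progress_csv(path: str | Path,
                       curves: Sequence[ProgressCurve]) -> None:
    rows = [
        {"condition_id": c.condition_id, "s0_uM": c.s0_uM,
         "time_h": t, "product_uM": p}
        for c in curves
        for t, p in zip(c.times_h, c.product_uM)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_progress_csv(path: str | Path) -> list[ProgressCurve]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("condition_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(ProgressCurve(
            grp["time_h"].to_numpy(float), grp["product_uM"].to_numpy(float),
            float(grp["s0_uM"].iloc[0]), condition_id=str(cid),
        ))
    return out


# -- conditions -------------------------------------------------------------

def write_conditions_csv(path: str | Path,
                         conds: Sequence[ReactionConditions]) -> None:
    pd.DataFrame([asdict(c) for c in conds]).to_csv(path, index=False)


def read_conditions_csv(path: str | Path) -> list[ReactionConditions]:
    df = pd.read_csv(path)
    return [
        ReactionConditions(
            float(r.substrate_uM), float(r.conjugate_uM),
            float(r.volume_ul) if "volume_ul" in df.columns else 100.0,
        )
        for _, r in df.iterrows()
    ]


# -- model parameters -------------------------------------------------------

def dump_params(path: str | Path, eq: EquilibriumParams,
                kin: KineticParams) -> None:
    Path(path).write_text(json.dumps(
        {"equilibrium": asdict(eq), "kinetic": asdict(kin)}, indent=2,
    ) + "\n")


def load_params(source: str | Path) -> tuple[EquilibriumParams, KineticParams]:
    """Model parameters from a JSON file or a named preset.

    JSON schema: ``{"equilibrium": {...}, "kinetic": {...}}`` with the
    field names of :class:`EquilibriumParams`/:class:`KineticParams`.
    Preset names: ``paper-like``, ``activation-demo``,
    ``inactivation-demo``.
    """
    from . import presets

    names = {
        "paper-like": presets.paper_like,
        "activation-demo": presets.activation_demo,
        "inactivation-demo": presets.inactivation_demo,
    }
    if str(source) in names:
        return names[str(source)]()
    data = json.loads(Path(source).read_text())
    return (EquilibriumParams(**data["equilibrium"]),
            KineticParams(**data["kinetic"]))


# -- fixtures ---------------------------------------------------------------

def write_assay_fixture(fix: AssayFixture, outdir: str | Path) -> dict:
    """Write per-condition fluorescence CSVs plus a truth JSON.

    Returns the manifest (paths and SHA-256 hashes), which is also
    written to ``manifest.json``; identical seeds give identical
    hashes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for cond, fs in zip(fix.conditions, fix.series):
        p = out / f"fluor_excess_{cond.excess_ratio:g}.csv"
        write_fluorescence_csv(p, fs)
        paths.append(p)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(fix.truth, indent=2, sort_keys=True) + "\n")
    manifest = {
        "kind": "assay",
        "files": {p.name: file_sha256(p) for p in paths + [truth_path]},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def read_assay_fixture(outdir: str | Path) -> tuple[list[FluorescenceSeries],
                                                    list[ReactionConditions],
                                                    dict]:
    out = Path(outdir)
    truth = json.loads((out / "truth.json").read_text())
    conds = [ReactionConditions(**c) for c in truth["conditions"]]
    series = [
        read_fluorescence_csv(out / f"fluor_excess_{c.excess_ratio:g}.csv")
        for c in conds
    ]
    return series, conds, truth


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
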