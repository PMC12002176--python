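"""Shared readers/writers and run configuration.

FASTA goes through Bio.SeqIO; tabular inputs (sample sheets, cell
coordinate tables, region polygons, AIRR-style rearrangement tables)
through pandas. Two AIRR dialects are accepted: a wide per-cell form
(one row per cell, ``junction_vdj``/``junction_vj`` columns) and a long
per-chain form (one row per chain with a ``locus`` column, IGH for the
heavy VDJ chain and IGK/IGL for the light VJ chain).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clonotype import Rearrangement
from .spatial import CellPoint, GCRegion, SpatialSample

log = logging.getLogger("ectopicgc")

_WIDE_REQUIRED = ["cell_id", "junction_vdj", "junction_vj"]
_LONG_REQUIRED = ["cell_id", "locus", "junction"]
_HEAVY_LOCI = {"IGH"}
_LIGHT_LOCI = {"IGK", "IGL"}


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA with unique ids and upper-cased sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dupes}")
    for r in records:
        r.seq = Seq(str(r.seq).upper())
    return records


def write_fasta(records: Iterable, path: str | Path) -> None:
    out = []
    for r in records:
        if isinstance(r, SeqRecord):
            out.append(r)
        else:  # (id, seq) pair or object with read_id/seq
            if isinstance(r, tuple):
                rid, seq = r
            else:
                rid, seq = r.read_id, r.seq
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """CSV mapping read_id to group labels (mouse/tissue/timepoint/...)."""
    df = pd.read_csv(path, dtype=str)
    if "read_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'read_id'")
    if df.read_id.duplicated().any():
        raise ValueError(f"{path}: duplicate read_id entries")
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_airr(path: str | Path) -> list[Rearrangement]:
    """Read an AIRR-style TSV in wide (per-cell) or long (per-chain) form.

    Cells missing either chain are dropped with a logged count, matching
    the upstream rule that only cells with a single productive V(D)J
    pair enter clonotype analysis.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "junction_vdj" in df.columns:
        _require(df, _WIDE_REQUIRED, path)
        wide = df
    else:
        _require(df, _LONG_REQUIRED, path)
        wide = _long_to_wide(df)
    cells = []
    n_dropped = 0
    for _, row in wide.iterrows():
        if not row.get("junction_vdj") or not row.get("junction_vj"):
            n_dropped += 1
            continue
        cells.append(Rearrangement(
            cell_id=row["cell_id"],
            mouse=row.get("mouse", "m1") or "m1",
            tissue=row.get("tissue", "") or "",
            compartment=row.get("compartment", "") or "",
            junction_vdj=row["junction_vdj"],
            junction_vj=row["junction_vj"],
            v_call_vdj=row.get("v_call_vdj") or None,
            j_call_vdj=row.get("j_call_vdj") or None,
            v_call_vj=row.get("v_call_vj") or None,
            j_call_vj=row.get("j_call_vj") or None,
        ))
    if n_dropped:
        log.warning("%s: dropped %d cell(s) missing a chain", path, n_dropped)
    return cells


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for _, r in df.iterrows():
        cell = rows.setdefault(r["cell_id"], {
            "cell_id": r["cell_id"],
            "mouse": r.get("mouse", "m1"),
            "tissue": r.get("tissue", ""),
            "compartment": r.get("compartment", ""),
        })
        locus = r["locus"].upper()
        if locus in _HEAVY_LOCI:
            cell["junction_vdj"] = r["junction"]
            cell["v_call_vdj"] = r.get("v_call", "")
            cell["j_call_vdj"] = r.get("j_call", "")
        elif locus in _LIGHT_LOCI:
            cell["junction_vj"] = r["junction"]
            cell["v_call_vj"] = r.get("v_call", "")
            cell["j_call_vj"] = r.get("j_call", "")
        else:
            raise ValueError(f"unknown locus {r['locus']!r}")
    return pd.DataFrame(rows.values())


def write_airr(cells: Sequence[Rearrangement], path: str | Path) -> None:
    """Write the wide per-cell AIRR-style TSV."""
    pd.DataFrame([
        dict(cell_id=c.cell_id, mouse=c.mouse, tissue=c.tissue,
             compartment=c.compartment, junction_vdj=c.junction_vdj,
             junction_vj=c.junction_vj,
             v_call_vdj=c.v_call_vdj or "", j_call_vdj=c.j_call_vdj or "",
             v_call_vj=c.v_call_vj or "", j_call_vj=c.j_call_vj or "")
        for c in cells
    ]).to_csv(path, sep="\t", index=False)


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["gc_id", "x", "y", "cell_type"], path)
    return df


def read_regions_csv(path: str | Path) -> dict[str, GCRegion]:
    """Region CSV (gc_id, vertex_order, x, y) to polygons per GC."""
    df = pd.read_csv(path)
    _require(df, ["gc_id", "vertex_order", "x", "y"], path)
    regions = {}
    for gc_id, g in df.groupby("gc_id"):
        g = g.sort_values("vertex_order")
        regions[str(gc_id)] = GCRegion(tuple(zip(g.x, g.y)))
    return regions


def load_spatial_samples(cells_path: str | Path,
                         regions_path: str | Path) -> list[SpatialSample]:
    cells = read_cells_csv(cells_path)
    regions = read_regions_csv(regions_path)
    samples = []
    for gc_id, g in cells.groupby("gc_id"):
        gc_id = str(gc_id)
        if gc_id not in regions:
            raise ValueError(f"no region polygon for GC {gc_id!r}")
        pts = [CellPoint(r.x, r.y, r.cell_type) for r in g.itertuples()]
        samples.append(SpatialSample(gc_id, regions[gc_id], pts))
    return samples


def write_spatial_csvs(samples: Sequence[SpatialSample],
                       cells_path: str | Path,
                       regions_path: str | Path) -> None:
    cell_rows, region_rows = [], []
    for s in samples:
        for c in s.cells:
            cell_rows.append(dict(gc_id=s.gc_id, x=c.x, y=c.y,
                                  cell_type=c.cell_type))
        for k, (x, y) in enumerate(s.region.vertices):
            region_rows.append(dict(gc_id=s.gc_id, vertex_order=k, x=x, y=y))
    pd.DataFrame(cell_rows).to_csv(cells_path, index=False)
    pd.DataFrame(region_rows).to_csv(regions_path, index=False)


_CONFIG_RANGES = {
    "min_similarity": (0.0, 1.0),
    "min_coverage": (0.0, 1.0),
    "tol": (0.0, float("inf")),
    "min_gc_cells": (1, 10_000),
    "key_codon": (1, 10_000),
    "pixel_size": (0.0, float("inf")),
}


@dataclass
class RunConfig:
    """Validated per-run parameters, serialized into every output dir."""

    seed: int = 0
    key_codon: int = 33
    min_coverage: float = 0.9
    min_similarity: float = 0.85
    min_gc_cells: int = 3
    tol: float = 0.0
    pixel_size: float = 0.170  # µm/pixel for mask-derived coordinates

    def __post_init__(self) -> None:
        for key, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, key, None)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bad = set(raw) - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def dump(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "run_config.yaml"
        out.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return out


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int,
                   inputs: Sequence[str | Path] = (),
                   **extra) -> Path:
    """Machine-readable provenance for one pipeline run."""
    from . import __version__
    manifest = {
        "tool": "ectopicgc",
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): file_checksum(p) for p in inputs},
        **extra,
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
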