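#!/usr/bin/env python
"""Generate the ground-truthed synthetic inputs for the downstream stages.

Emulates the three experimental readouts: Sanger reads of the germline
heavy-chain V window from sorted GC B cells (lung lags the lymph node in
acquiring the high-affinity W33L mutation, so the lung gets a lower
forcing probability at the early timepoint), imaged GC point patterns
at a range of polarization strengths, and a paired-junction B-cell
repertoire spread over tissue and GC/memory compartments.

Writes FASTA/CSV/TSV inputs plus truth JSON under results/sim/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ectopicgc import io as eio
from ectopicgc import synthetic as syn
from ectopicgc.spatial import GCRegion

SEED = 20250901
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

# W33L forcing probabilities per (tissue, timepoint): the early lung GC
# lags the node, converging by the late timepoint
CONDITIONS = {
    ("lung", "d14"): 0.18,
    ("medLN", "d14"): 0.67,
    ("lung", "d21"): 0.59,
    ("medLN", "d21"): 0.54,
}
N_READS = 120  # per condition
MU = 0.01  # per-base substitution rate over the 297-nt window


def simulate_shm(out: Path) -> None:
    ref = syn.make_reference(n_codons=99, seed=SEED)
    eio.write_fasta([(ref.name, ref.seq)], out / "reference.fasta")
    all_reads, sheet, truths = [], [], []
    for i, ((tissue, day), p_w33l) in enumerate(sorted(CONDITIONS.items())):
        reads, truth = syn.simulate_shm_reads(
            ref, N_READS, mu=MU, p_w33l=p_w33l,
            indel_rate=0.02, n_rate=0.002, seed=SEED + i + 1)
        for r, t in zip(reads, truth):
            rid = f"{tissue}_{day}_{r.read_id}"
            all_reads.append((rid, r.seq))
            sheet.append(dict(read_id=rid, tissue=tissue, timepoint=day))
            d = dataclasses.asdict(t)
            d["read_id"] = rid
            truths.append(d)
    eio.write_fasta(all_reads, out / "reads.fasta")
    pd.DataFrame(sheet).to_csv(out / "sheet.csv", index=False)
    (out / "shm_truth.json").write_text(json.dumps(truths))
    print(f"shm: {len(all_reads)} reads across {len(CONDITIONS)} conditions")


def simulate_spatial(out: Path) -> None:
    # lymph-node GCs are drawn larger than lung GCs; both polarized
    ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    rows_cells, rows_regions, truth = [], [], {}
    rng = np.random.default_rng(SEED)
    for k in range(12):
        tissue = "medLN" if k < 6 else "lung"
        radius = rng.uniform(80, 120) if tissue == "medLN" else rng.uniform(30, 55)
        region = GCRegion(tuple(zip(radius * np.cos(ang), radius * np.sin(ang))))
        gc_id = f"{tissue}_gc{k}"
        pi = float(rng.uniform(0.7, 0.95))
        n_cells = int(radius * rng.uniform(1.5, 2.5))
        sample, t = syn.simulate_gc_sample(
            n_cells, pi, region, seed=SEED + 100 + k, cell_type="Tfh",
            gc_id=gc_id)
        truth[gc_id] = dict(pi=t.pi, tissue=tissue, radius=radius)
        for c in sample.cells:
            rows_cells.append(dict(gc_id=gc_id, x=c.x, y=c.y, cell_type=c.cell_type))
        for v, (x, y) in enumerate(region.vertices):
            rows_regions.append(dict(gc_id=gc_id, vertex_order=v, x=x, y=y))
    pd.DataFrame(rows_cells).to_csv(out / "cells.csv", index=False)
    pd.DataFrame(rows_regions).to_csv(out / "regions.csv", index=False)
    (out / "spatial_truth.json").write_text(json.dumps(truth))
    print(f"spatial: 12 GCs, {len(rows_cells)} cells")


def simulate_repertoire(out: Path) -> None:
    # clones are mostly tissue-restricted: each clone has a home tissue
    # and only occasionally seeds a member in the other one
    homes = {"lung": {"lung": 0.95, "mLN": 0.05},
             "mLN": {"lung": 0.05, "mLN": 0.95}}
    frames = []
    truth = {}
    k = 0
    for mouse in ["m1", "m2"]:
        for home, tissue_probs in sorted(homes.items()):
            cells, t = syn.simulate_repertoire(
                n_clones=30, mean_clone_size=4.0, within_clone_div=0.05,
                tissue_probs=tissue_probs,
                compartment_probs={"GC": 0.75, "MBC": 0.25},
                mouse=mouse, seed=SEED + 200 + k)
            k += 1
            # cell ids repeat across calls; disambiguate with a prefix
            prefix = f"{mouse}_{home}"
            frames.extend(
                dataclasses.replace(c, cell_id=f"{prefix}_{c.cell_id}")
                for c in cells)
            truth.update({f"{prefix}_{cid}": f"{prefix}:{lbl}"
                          for cid, lbl in t.clone_of.items()})
    eio.write_airr(frames, out / "repertoire.tsv")
    (out / "repertoire_truth.json").write_text(json.dumps(truth))
    print(f"repertoire: {len(frames)} cells in 2 mice")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    simulate_shm(OUT)
    simulate_spatial(OUT)
    simulate_repertoire(OUT)
    eio.write_manifest(OUT, seed=SEED)


if __name__ == "__main__":
    main()
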