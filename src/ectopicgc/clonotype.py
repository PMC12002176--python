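"""Clonotype clustering of paired-chain BCR junctions.

Cells carrying a single productive heavy (VDJ) and light (VJ) chain are
clustered into clonotypes: two cells belong to the same clone when both
junction pairs are at least ``min_similarity`` identical under the
normalized Hamming similarity (1 − mismatches/length for equal-length
junctions, 0 otherwise), taking single-linkage connected components.
Downstream statistics follow the study design: clonal expansions are
clones with ≥3 germinal-center members; tissue overlap (lung vs
mediastinal lymph node) and the percentage of GC clones re-found in the
memory B-cell (MBC) pool quantify cross-tissue and GC→memory sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Rearrangement",
    "CloneSet",
    "SharingSummary",
    "junction_similarity",
    "cluster_clonotypes",
    "expanded_clones",
    "sharing_stats",
]


@dataclass(frozen=True)
class Rearrangement:
    """One cell's paired junctions with its tissue/compartment labels."""

    cell_id: str
    mouse: str
    tissue: str  # e.g. "lung" | "mLN"
    compartment: str  # "GC" | "MBC"
    junction_vdj: str  # heavy chain
    junction_vj: str  # light chain
    v_call_vdj: str | None = None
    j_call_vdj: str | None = None
    v_call_vj: str | None = None
    j_call_vj: str | None = None

    def __post_init__(self) -> None:
        if not self.junction_vdj or not self.junction_vj:
            raise ValueError(f"cell {self.cell_id}: both junctions are required")


def junction_similarity(a: str, b: str) -> float:
    """Normalized Hamming similarity between two junctions.

    Equal lengths: 1 − mismatches/length (case-insensitive; N mismatches
    everything, including another N). Unequal lengths: 0.0 — Hamming
    distance is undefined across lengths, so such junctions never match.
    """
    if not a or not b:
        raise ValueError("empty junction sequence")
    if len(a) != len(b):
        return 0.0
    a, b = a.upper(), b.upper()
    mismatches = sum(
        x != y or x == "N" for x, y in zip(a, b)
    )
    return 1.0 - mismatches / len(a)


def _cells_match(x: Rearrangement, y: Rearrangement, min_similarity: float,
                 require_same_vj: bool, both_chains: bool) -> bool:
    sim_h = junction_similarity(x.junction_vdj, y.junction_vdj)
    sim_l = junction_similarity(x.junction_vj, y.junction_vj)
    ok = (sim_h >= min_similarity and sim_l >= min_similarity) if both_chains \
        else (sim_h >= min_similarity or sim_l >= min_similarity)
    if ok and require_same_vj:
        ok = (
            x.v_call_vdj == y.v_call_vdj and x.j_call_vdj == y.j_call_vdj
            and x.v_call_vj == y.v_call_vj and x.j_call_vj == y.j_call_vj
        )
    return ok


@dataclass
class CloneSet:
    """Partition of cells into clonotype clusters.

    ``membership``: cell_id → clone_id (tidy frame with the cell labels);
    ``clones``: one row per clone with size and per-(tissue, compartment)
    member counts. Clone ids are deterministic: numbered by decreasing
    size, ties broken by the lexicographically smallest member cell_id,
    prefixed with the mouse when mice are clustered independently.
    """

    membership: pd.DataFrame
    clones: pd.DataFrame

    def __len__(self) -> int:
        return len(self.clones)

    def labels(self) -> pd.Series:
        """clone_id indexed by cell_id (for partition comparisons)."""
        return self.membership.set_index("cell_id")["clone_id"]


def _cluster_one_group(cells: Sequence[Rearrangement], min_similarity: float,
                       require_same_vj: bool, both_chains: bool,
                       linkage: str) -> list[list[Rearrangement]]:
    g = nx.Graph()
    g.add_nodes_from(range(len(cells)))
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if _cells_match(cells[i], cells[j], min_similarity,
                            require_same_vj, both_chains):
                g.add_edge(i, j)
    if linkage == "single":
        comps = nx.connected_components(g)
    elif linkage == "complete":
        comps = _disjoint_cliques(g)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    return [[cells[i] for i in comp] for comp in comps]


def _disjoint_cliques(g: nx.Graph) -> list[set[int]]:
    """Greedy complete-linkage: repeatedly take the largest remaining clique."""
    remaining = set(g.nodes)
    out: list[set[int]] = []
    while remaining:
        sub = g.subgraph(remaining)
        best = max(nx.find_cliques(sub), key=lambda c: (len(c), sorted(c)))
        out.append(set(best))
        remaining -= set(best)
    return out


def cluster_clonotypes(cells: Iterable[Rearrangement],
                       min_similarity: float = 0.85,
                       require_same_vj: bool = False,
                       both_chains: bool = True,
                       per_mouse: bool = True,
                       linkage: str = "single") -> CloneSet:
    """Cluster cells into clonotypes by paired-junction similarity.

    An edge joins two cells when the heavy and light junction
    similarities both reach ``min_similarity`` (AND rule; set
    ``both_chains=False`` for OR); clones are single-linkage connected
    components. Mice are clustered independently by default.
    """
    cells = list(cells)
    if not cells:
        empty = pd.DataFrame(columns=["cell_id", "mouse", "tissue",
                                      "compartment", "clone_id"])
        return CloneSet(empty, pd.DataFrame(columns=["clone_id", "size"]))
    groups: dict[str, list[Rearrangement]]
    if per_mouse:
        groups = {}
        for c in cells:
            groups.setdefault(c.mouse, []).append(c)
    else:
        groups = {"pooled": cells}

    clusters: list[tuple[str, list[Rearrangement]]] = []
    for mouse in sorted(groups):
        for comp in _cluster_one_group(groups[mouse], min_similarity,
                                       require_same_vj, both_chains, linkage):
            clusters.append((mouse, comp))

    # deterministic ids: size desc, then smallest member cell_id
    clusters.sort(key=lambda mc: (-len(mc[1]), min(c.cell_id for c in mc[1])))
    width = len(str(len(clusters)))
    mem_rows, clone_rows = [], []
    for k, (mouse, members) in enumerate(clusters, start=1):
        clone_id = f"{mouse}:clone{k:0{width}d}" if per_mouse else f"clone{k:0{width}d}"
        counts: dict[tuple[str, str], int] = {}
        for c in members:
            counts[(c.tissue, c.compartment)] = counts.get((c.tissue, c.compartment), 0) + 1
            mem_rows.append(dict(cell_id=c.cell_id, mouse=c.mouse,
                                 tissue=c.tissue, compartment=c.compartment,
                                 clone_id=clone_id))
        row = dict(clone_id=clone_id, mouse=mouse, size=len(members))
        for (t, cp), n in sorted(counts.items()):
            row[f"n_{t}_{cp}"] = n
        clone_rows.append(row)
    clones = pd.DataFrame(clone_rows).fillna(0)
    count_cols = [c for c in clones.columns if c.startswith("n_")]
    clones[count_cols] = clones[count_cols].astype(int)
    return CloneSet(pd.DataFrame(mem_rows), clones)


def _gc_members(clone_members: pd.DataFrame) -> pd.DataFrame:
    return clone_members[clone_members.compartment == "GC"]


def expanded_clones(clones: CloneSet, min_gc_cells: int = 3) -> CloneSet:
    """Clones with at least ``min_gc_cells`` germinal-center members.

    The threshold applies to GC-compartment members only; memory cells do
    not make a clone "expanded". The returned subset keeps the original
    clone ids, with a ``gc_tissue_class`` column partitioning expanded
    clones into lung-only / mLN-only / shared by the tissues of their GC
    members.
    """
    mem = clones.membership
    gc_counts = _gc_members(mem).groupby("clone_id").size()
    keep = gc_counts[gc_counts >= min_gc_cells].index
    sub_clones = clones.clones[clones.clones.clone_id.isin(keep)].copy()
    sub_mem = mem[mem.clone_id.isin(keep)].copy()

    tissue_sets = _gc_members(sub_mem).groupby("clone_id")["tissue"].agg(set)
    def classify(ts: set) -> str:
        return "shared" if len(ts) > 1 else f"{next(iter(ts))}-only"
    sub_clones["gc_tissue_class"] = sub_clones.clone_id.map(
        tissue_sets.map(classify))
    return CloneSet(sub_mem, sub_clones)


@dataclass
class SharingSummary:
    """Per-mouse tissue Venn of GC clones and GC→MBC sharing matrix.

    ``venn[mouse]`` holds lung_only / mLN_only / shared counts over
    distinct clones with ≥1 GC member. ``pct.loc[t, u]`` is the
    percentage of clones with a GC member in tissue ``t`` that also have
    ≥1 MBC member in tissue ``u``; NaN where a tissue has no GC clones.
    """

    venn: dict[str, dict[str, int]]
    pct: pd.DataFrame
    n_gc_clones: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def sharing_stats(clones: CloneSet, tissues: Sequence[str] | None = None) -> SharingSummary:
    """Cross-tissue Venn counts and GC→MBC sharing percentages."""
    mem = clones.membership
    if tissues is None:
        tissues = sorted(mem.tissue.unique()) if len(mem) else []

    gc = _gc_members(mem)
    mbc = mem[mem.compartment == "MBC"]
    gc_tissues = gc.groupby("clone_id")["tissue"].agg(set)
    mbc_tissues = mbc.groupby("clone_id")["tissue"].agg(set)

    venn: dict[str, dict[str, int]] = {}
    for mouse, g in gc.groupby("mouse"):
        ts = g.groupby("clone_id")["tissue"].agg(set)
        counts = {f"{t}_only": int(sum(s == {t} for s in ts)) for t in tissues}
        counts["shared"] = int(sum(len(s) > 1 for s in ts))
        venn[str(mouse)] = counts

    pct = pd.DataFrame(index=list(tissues), columns=list(tissues), dtype=float)
    n_gc = pd.Series(0, index=list(tissues), dtype=int)
    for t in tissues:
        source = [cid for cid, s in gc_tissues.items() if t in s]
        n_gc[t] = len(source)
        for u in tissues:
            if not source:
                pct.loc[t, u] = np.nan
                continue
            hit = sum(u in mbc_tissues.get(cid, set()) for cid in source)
            pct.loc[t, u] = 100.0 * hit / len(source)
    pct.index.name = "gc_tissue"
    pct.columns.name = "mbc_tissue"
    return SharingSummary(venn, pct, n_gc)
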