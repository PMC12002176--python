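"""Ground-truthed simulators for every pipeline stage.

Three generators emulate the statistical structure the analyses assume,
so the whole pipeline is testable without any external data:

* ``simulate_shm_reads`` — point-mutated reads derived from a
  codon-framed germline with a tryptophan at the key codon, with tunable
  per-base substitution rate, probability of forcing the high-affinity
  W→L change, and optional single indels / N masking;
* ``simulate_gc_sample`` — 2-D point patterns inside a GC polygon with a
  tunable polarization parameter π (probability mass on a randomly
  oriented half through the centroid);
* ``simulate_repertoire`` — clonal repertoires with a clone-size
  distribution, within-clone junction divergence, and tissue/compartment
  assignment probabilities.

Every simulator takes an explicit seed, is deterministic under it, and
returns a truth record alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point

from .clonotype import Rearrangement
from .shm import GermlineReference, SangerRead, translate_codon
from .spatial import CellPoint, GCRegion, SpatialSample, region_centroid

__all__ = [
    "ShmTruth",
    "SpatialTruth",
    "RepertoireTruth",
    "make_reference",
    "simulate_shm_reads",
    "simulate_gc_sample",
    "simulate_repertoire",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ShmTruth:
    """Per-read record of every injected event."""

    read_id: str
    substituted_positions: tuple[int, ...]  # 0-based within the window
    codon33_class: str  # class of the emitted read's key codon
    n_replacement: int  # under the final-codon comparison convention
    n_silent: int
    has_indel: bool
    n_positions: tuple[int, ...]


@dataclass
class SpatialTruth:
    pi: float
    direction: tuple[float, float]  # unit normal of the designated half
    seed: int


@dataclass
class RepertoireTruth:
    clone_of: dict[str, str]  # cell_id -> true clone label
    founders: dict[str, tuple[str, str]] = field(default_factory=dict)


def make_reference(n_codons: int = 99, seed: int = 0,
                   key_codon_index: int = 33,
                   name: str = "synthetic_vh") -> GermlineReference:
    """Random stop-free codon sequence with TGG forced at the key codon."""
    if n_codons < key_codon_index + 1:
        raise ValueError(
            f"need at least {key_codon_index + 1} codons, got {n_codons}")
    rng = np.random.default_rng(seed)
    codons = []
    for i in range(n_codons):
        if i == key_codon_index - 1:
            codons.append("TGG")
            continue
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3))
            if codon not in _STOPS:
                break
        codons.append(codon)
    return GermlineReference(name=name, seq="".join(codons),
                             key_codon_index=key_codon_index)


def _true_rs_counts(ref_window: str, read: str) -> tuple[int, int]:
    """Codon-wise recount of R/S from the final sequences (same length)."""
    n_r = n_s = 0
    for start in range(0, len(ref_window), 3):
        rc, qc = ref_window[start:start + 3], read[start:start + 3]
        if "N" in qc:
            continue
        diff = sum(a != b for a, b in zip(rc, qc))
        if diff:
            if translate_codon(rc) != translate_codon(qc):
                n_r += diff
            else:
                n_s += diff
    return n_r, n_s


def _codon33_class(read: str, ref: GermlineReference) -> str:
    i = ref.key_codon_index
    codon = read[3 * (i - 1): 3 * i]
    if "N" in codon or len(codon) < 3:
        return "Undetermined"
    aa = translate_codon(codon)
    return {"W": "W", "L": "L"}.get(aa, "Other")


def simulate_shm_reads(ref: GermlineReference, n_reads: int,
                       mu: float = 0.005, p_w33l: float = 0.0,
                       indel_rate: float = 0.0, n_rate: float = 0.0,
                       seed: int = 0) -> tuple[list[SangerRead], list[ShmTruth]]:
    """Emit point-mutated copies of the reference window with truth.

    Substitutions are i.i.d. per base at rate ``mu`` (uniform over the 3
    alternative bases). With probability ``p_w33l`` the key codon is then
    forced to TTG (the single-nucleotide W→L change), overriding any
    substitution there. With probability ``indel_rate`` a single 1-nt
    indel is placed at a uniform position; bases are masked to N
    independently at ``n_rate``. The truth records the post-hoc R/S
    counts of the emitted read under the final-codon convention, so it is
    consistent with the read by construction even when events overlap.
    """
    for p, nm in [(mu, "mu"), (p_w33l, "p_w33l"),
                  (indel_rate, "indel_rate"), (n_rate, "n_rate")]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    window = ref.window
    L = len(window)
    key0 = 3 * (ref.key_codon_index - 1)
    reads, truths = [], []
    for i in range(n_reads):
        seq = list(window)
        sub_mask = rng.random(L) < mu
        for pos in np.flatnonzero(sub_mask):
            alts = [b for b in _BASES if b != seq[pos]]
            seq[pos] = alts[rng.integers(3)]
        if rng.random() < p_w33l:
            seq[key0:key0 + 3] = list("TTG")
        sub_positions = tuple(
            p for p in range(L) if seq[p] != window[p]
        )
        mutated = "".join(seq)

        # N masking precedes the indel so the truth counts (taken on the
        # masked, frame-intact sequence) match the pipeline on every
        # non-excluded read by construction.
        n_mask = rng.random(L) < n_rate
        n_positions = tuple(int(p) for p in np.flatnonzero(n_mask))
        if n_positions:
            chars = list(mutated)
            for p in n_positions:
                chars[p] = "N"
            mutated = "".join(chars)
        n_r, n_s = _true_rs_counts(window, mutated)
        codon33 = _codon33_class(mutated, ref)

        has_indel = bool(rng.random() < indel_rate)
        if has_indel:
            # keep the indel well inside the window: an indel within a
            # couple of bases of either end is indistinguishable from a
            # truncated read and reads as coverage, not frameshift
            pos = int(rng.integers(3, L - 3))
            if rng.random() < 0.5:
                mutated = mutated[:pos] + mutated[pos + 1:]
            else:
                ins = _BASES[rng.integers(4)]
                mutated = mutated[:pos] + ins + mutated[pos:]

        read_id = f"read{i:05d}"
        reads.append(SangerRead(read_id, mutated))
        truths.append(ShmTruth(read_id, sub_positions, codon33,
                               n_r, n_s, has_indel, n_positions))
    return reads, truths


def _uniform_in(polygon, rng: np.random.Generator, n: int,
                side_sign: int | None = None,
                direction: np.ndarray | None = None,
                centroid: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample uniform points in a polygon (optionally a half)."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    k = 0
    while k < n:
        m = max(4 * (n - k), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if not polygon.contains(Point(x, y)):
                continue
            if side_sign is not None:
                s = float(np.dot(direction, np.array([x, y]) - centroid))
                if s * side_sign <= 0:
                    continue
            out[k] = (x, y)
            k += 1
            if k == n:
                break
    return out


def simulate_gc_sample(n_cells: int, pi: float, region: GCRegion,
                       seed: int = 0, cell_type: str = "Tfh",
                       gc_id: str = "sim") -> tuple[SpatialSample, SpatialTruth]:
    """Point pattern with probability mass ``pi`` on a random half.

    A random half of the region through its centroid is designated; each
    cell lands in the designated half with probability ``pi`` and is
    uniform within its half. ``pi=0.5`` is the uniform (unpolarized)
    null; ``pi=1.0`` confines the type entirely to one half.
    """
    if not 0.5 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0.5, 1.0], got {pi}")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])
    c = np.array(region_centroid(region))
    poly = region.polygon

    sides = np.where(rng.random(n_cells) < pi, 1, -1)
    cells: list[CellPoint] = []
    for sign in (1, -1):
        k = int(np.sum(sides == sign))
        if k:
            pts = _uniform_in(poly, rng, k, side_sign=sign,
                              direction=u, centroid=c)
            cells.extend(CellPoint(x, y, cell_type) for x, y in pts)
    sample = SpatialSample(gc_id=gc_id, region=region, cells=cells)
    return sample, SpatialTruth(pi=pi, direction=(u[0], u[1]), seed=seed)


def _random_junction(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(rate * len) distinct positions.

    The mutation count is fixed at its expectation so within-clone
    divergence is controlled exactly: any two members of a clone differ
    from each other at no more than 2*rate per base.
    """
    k = round(rate * len(seq))
    if k == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=k, replace=False):
        alts = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alts[rng.integers(3)]
    return "".join(chars)


def simulate_repertoire(n_clones: int = 50,
                        mean_clone_size: float = 4.0,
                        junction_len_range: tuple[int, int] = (36, 60),
                        within_clone_div: float = 0.05,
                        tissue_probs: dict[str, float] | None = None,
                        compartment_probs: dict[str, float] | None = None,
                        mouse: str = "m1",
                        max_founder_identity: float = 0.70,
                        seed: int = 0,
                        max_attempts: int = 2000,
                        ) -> tuple[list[Rearrangement], RepertoireTruth]:
    """Clonal repertoire with known clone labels.

    Each clone gets a founder junction pair (heavy length drawn from
    ``junction_len_range``, light 6 nt shorter); founders of equal
    length are rejection-sampled until every pairwise identity is below
    ``max_founder_identity``, so distinct clones stay well below any
    sensible clustering threshold. Clone sizes are 1 + Poisson
    (mean ``mean_clone_size − 1``); members carry the founder junctions
    mutated at ``within_clone_div`` per base, and draw tissue and
    compartment labels independently from the given probabilities.
    """
    tissue_probs = tissue_probs or {"lung": 0.5, "mLN": 0.5}
    compartment_probs = compartment_probs or {"GC": 0.7, "MBC": 0.3}
    rng = np.random.default_rng(seed)

    founders: dict[str, tuple[str, str]] = {}
    heavy_by_len: dict[int, list[str]] = {}
    for k in range(n_clones):
        for attempt in range(max_attempts):
            lh = int(rng.integers(junction_len_range[0], junction_len_range[1] + 1))
            heavy = _random_junction(rng, lh)
            light = _random_junction(rng, max(lh - 6, 12))
            clash = any(
                sum(a == b for a, b in zip(heavy, other)) / lh >= max_founder_identity
                for other in heavy_by_len.get(lh, [])
            )
            if not clash:
                break
        else:
            raise RuntimeError(
                "could not draw sufficiently distinct founders; "
                "raise junction length or lower n_clones")
        heavy_by_len.setdefault(lh, []).append(heavy)
        founders[f"true{k:03d}"] = (heavy, light)

    t_names, t_p = zip(*sorted(tissue_probs.items()))
    c_names, c_p = zip(*sorted(compartment_probs.items()))
    cells: list[Rearrangement] = []
    clone_of: dict[str, str] = {}
    i = 0
    for label, (heavy, light) in founders.items():
        size = 1 + int(rng.poisson(max(mean_clone_size - 1.0, 0.0)))
        for _ in range(size):
            cell_id = f"cell{i:05d}"
            i += 1
            cells.append(Rearrangement(
                cell_id=cell_id,
                mouse=mouse,
                tissue=str(rng.choice(t_names, p=t_p)),
                compartment=str(rng.choice(c_names, p=c_p)),
                junction_vdj=_mutate(heavy, within_clone_div, rng),
                junction_vj=_mutate(light, within_clone_div, rng),
            ))
            clone_of[cell_id] = label
    return cells, RepertoireTruth(clone_of=clone_of, founders=founders)
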