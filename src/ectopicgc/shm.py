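"""Somatic-hypermutation calling against a germline V segment.

This module aligns Sanger reads from sorted germinal-center B cells to a
codon-framed germline heavy-chain V reference (a V_H186.2-style consensus),
classifies the affinity-critical "codon 33" (tryptophan in the germline;
a leucine there marks the high-affinity W33L mutant), and counts
replacement and silent nucleotide mutations per read and per group.

Conventions
-----------
* Codon numbering is sequential within the supplied reference window
  (1-based); the key codon index is configurable and defaults to 33.
* Any alignment gap inside the analyzed window excludes a read from
  mutation counting ("frameshift"): replacement/silent counting presumes
  an intact codon frame.
* In a codon carrying several substitutions, every mismatching nucleotide
  inherits the codon-level class: replacement iff the translated germline
  and read amino acids differ (final-codon comparison, not a
  one-mutation-at-a-time decomposition).
* Codons containing an ambiguous base (N) contribute nothing; an N in the
  key codon yields the class ``Undetermined``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

__all__ = [
    "GermlineReference",
    "SangerRead",
    "CodonAlignment",
    "MutationRecord",
    "MutationProfile",
    "AlignmentParams",
    "load_reference",
    "align_to_reference",
    "classify_codon33",
    "count_rs_mutations",
    "summarize_groups",
]

_DNA = set("ACGT")
_LEUCINE_CODONS = {"TTA", "TTG", "CTT", "CTC", "CTA", "CTG"}


def translate_codon(codon: str) -> str:
    """Translate one codon to a one-letter amino acid ('*' for stop)."""
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GermlineReference:
    """Codon-framed germline V nucleotide sequence.

    ``seq`` is the full record; the analyzed window starts at
    ``frame_offset`` and spans a whole number of codons. The key codon
    (default index 33, 1-based) must encode tryptophan (TGG).
    """

    name: str
    seq: str
    frame_offset: int = 0
    key_codon_index: int = 33

    def __post_init__(self) -> None:
        if not set(self.seq) <= _DNA:
            bad = sorted(set(self.seq) - _DNA)
            raise ValueError(f"ambiguous base in reference: {bad}")
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be >= 0")
        if self.n_codons < 1:
            raise ValueError("reference window contains no full codon")
        if not 1 <= self.key_codon_index <= self.n_codons:
            raise ValueError(
                f"key codon index {self.key_codon_index} outside window "
                f"of {self.n_codons} codons"
            )
        aa = translate_codon(self.key_codon(self.window))
        if aa != "W":
            raise ValueError(f"key codon is {aa}, expected W")

    @property
    def n_codons(self) -> int:
        return (len(self.seq) - self.frame_offset) // 3

    @property
    def window(self) -> str:
        """In-frame analyzed window (length = 3 * n_codons)."""
        start = self.frame_offset
        return self.seq[start : start + 3 * self.n_codons]

    def codon(self, index: int) -> str:
        """1-based codon lookup within the window."""
        return self.window[3 * (index - 1) : 3 * index]

    def key_codon(self, window: str | None = None) -> str:
        w = self.window if window is None else window
        i = self.key_codon_index
        return w[3 * (i - 1) : 3 * i]


@dataclass(frozen=True)
class SangerRead:
    """One sequenced read with its sort metadata (mouse, tissue, ...)."""

    read_id: str
    seq: str
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.seq.upper()) - (_DNA | {"N"})
        if bad:
            raise ValueError(f"read {self.read_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass
class CodonAlignment:
    """Per-codon pairing of a read against the reference window.

    ``codon_pairs`` maps the 1-based codon index to ``(ref_codon,
    read_codon)`` for every reference codon fully covered by the read
    without interruption. ``gap_flag`` is set when the alignment opens a
    gap inside the covered region; such reads are refused by mutation
    counting. ``coverage`` is the fraction of reference codons covered.
    """

    read_id: str
    codon_pairs: dict[int, tuple[str, str]]
    gap_flag: bool
    coverage: float


def load_reference(path: str | Path, key_codon_index: int = 33,
                   frame_offset: int = 0) -> GermlineReference:
    """Load a single-record germline V FASTA and validate its key codon."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single reference record, found {len(records)}")
    rec = records[0]
    return GermlineReference(
        name=rec.id,
        seq=str(rec.seq).upper(),
        frame_offset=frame_offset,
        key_codon_index=key_codon_index,
    )


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # Sanger amplicons may start/stop inside or outside the window; end
    # gaps are coverage, not mutations.
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_to_reference(read: SangerRead, ref: GermlineReference,
                       params: AlignmentParams | None = None) -> CodonAlignment:
    """Globally align a read to the reference window, codon-wise.

    Codon pairs are emitted only for reference codons whose three bases
    are contiguously aligned to read bases. Leading/trailing unaligned
    reference (a short read) lowers ``coverage``; an internal gap sets
    ``gap_flag``.
    """
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    aln = aligner.align(ref.window, read.seq.upper())[0]
    ref_blocks, read_blocks = (b.tolist() for b in aln.aligned)

    # >1 aligned block means the alignment opened an internal gap.
    gap_flag = len(ref_blocks) > 1

    read_seq = read.seq.upper()
    pos_to_read: dict[int, str] = {}
    for (t0, t1), (q0, q1) in zip(ref_blocks, read_blocks):
        for off in range(t1 - t0):
            pos_to_read[t0 + off] = read_seq[q0 + off]

    codon_pairs: dict[int, tuple[str, str]] = {}
    for idx in range(1, ref.n_codons + 1):
        start = 3 * (idx - 1)
        if all(start + k in pos_to_read for k in range(3)):
            ref_codon = ref.window[start : start + 3]
            read_codon = "".join(pos_to_read[start + k] for k in range(3))
            codon_pairs[idx] = (ref_codon, read_codon)

    coverage = len(codon_pairs) / ref.n_codons
    return CodonAlignment(read.read_id, codon_pairs, gap_flag, coverage)


def classify_codon33(aln: CodonAlignment, ref: GermlineReference) -> str:
    """Classify the affinity-critical codon: W, L, Other, or Undetermined.

    Any of the six leucine codons counts as L (the high-affinity W33L
    class); an uncovered key codon or one containing N is Undetermined;
    every other amino acid (including stop) is Other.
    """
    pair = aln.codon_pairs.get(ref.key_codon_index)
    if pair is None:
        return "Undetermined"
    read_codon = pair[1]
    if "N" in read_codon:
        return "Undetermined"
    if read_codon == "TGG":
        return "W"
    if read_codon in _LEUCINE_CODONS:
        return "L"
    return "Other"


@dataclass(frozen=True)
class MutationRecord:
    codon_index: int
    nt_positions_changed: tuple[int, ...]  # 1..3 within the codon
    ref_codon: str
    read_codon: str
    ref_aa: str
    read_aa: str
    klass: str  # "replacement" | "silent"


@dataclass
class MutationProfile:
    read_id: str
    codon33_class: str
    n_replacement: int
    n_silent: int
    records: list[MutationRecord]
    excluded: bool = False
    reason: str | None = None

    @property
    def n_total(self) -> int:
        return self.n_replacement + self.n_silent


def count_rs_mutations(aln: CodonAlignment, ref: GermlineReference,
                       min_coverage: float = 0.9) -> MutationProfile:
    """Count replacement/silent nucleotide mutations for one read.

    Reads with an internal gap are excluded with reason ``frameshift``;
    reads below ``min_coverage`` or missing the key codon are excluded
    with reason ``low_coverage``. Excluded profiles carry zero counts,
    never partial ones.
    """
    codon33 = classify_codon33(aln, ref)
    if aln.gap_flag:
        return MutationProfile(aln.read_id, codon33, 0, 0, [], True, "frameshift")
    if aln.coverage < min_coverage or ref.key_codon_index not in aln.codon_pairs:
        return MutationProfile(aln.read_id, codon33, 0, 0, [], True, "low_coverage")

    records: list[MutationRecord] = []
    n_r = n_s = 0
    for idx in sorted(aln.codon_pairs):
        ref_codon, read_codon = aln.codon_pairs[idx]
        if "N" in read_codon:
            continue
        changed = tuple(k + 1 for k in range(3) if ref_codon[k] != read_codon[k])
        if not changed:
            continue
        ref_aa = translate_codon(ref_codon)
        read_aa = translate_codon(read_codon)
        klass = "replacement" if ref_aa != read_aa else "silent"
        records.append(MutationRecord(idx, changed, ref_codon, read_codon,
                                      ref_aa, read_aa, klass))
        if klass == "replacement":
            n_r += len(changed)
        else:
            n_s += len(changed)
    return MutationProfile(aln.read_id, codon33, n_r, n_s, records)


def call_reads(reads: Iterable[SangerRead], ref: GermlineReference,
               params: AlignmentParams | None = None,
               min_coverage: float = 0.9) -> list[MutationProfile]:
    """Align, classify, and count every read: the per-read pipeline."""
    return [
        count_rs_mutations(align_to_reference(r, ref, params), ref, min_coverage)
        for r in reads
    ]


def profiles_frame(profiles: Sequence[MutationProfile]) -> pd.DataFrame:
    """Tidy per-read table: one row per profile."""
    return pd.DataFrame(
        {
            "read_id": p.read_id,
            "codon33_class": p.codon33_class,
            "n_replacement": p.n_replacement,
            "n_silent": p.n_silent,
            "n_total": p.n_total,
            "excluded": p.excluded,
            "reason": p.reason or "",
        }
        for p in profiles
    )


def summarize_groups(profiles: Sequence[MutationProfile],
                     meta: pd.DataFrame | None = None,
                     groupby: Sequence[str] = ()) -> pd.DataFrame:
    """Per-group codon-33 class fractions and pooled R/S sums.

    ``meta`` maps read_id to grouping labels (mouse, tissue, timepoint,
    compartment); with no grouping, one overall summary row is returned.
    Excluded reads contribute nothing; Undetermined reads are left out of
    the class fractions (reported as ``n_undetermined``) but their
    mutation counts still pool into sum_R/sum_S. ``rs_ratio`` is the
    pooled sum_R/sum_S, NaN-flagged when sum_S is zero.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    df = profiles_frame(profiles)
    if meta is not None:
        meta = meta.reset_index() if meta.index.name == "read_id" else meta
        df = df.merge(meta, on="read_id", how="left", validate="one_to_one")
    groupby = list(groupby)
    if not groupby:
        df["_all"] = "all"
        groupby = ["_all"]

    rows = []
    for keys, g in df.groupby(groupby, sort=True, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        kept = g[~g.excluded]
        classified = kept[kept.codon33_class != "Undetermined"]
        n_classified = len(classified)
        counts = classified.codon33_class.value_counts()
        sum_r = int(kept.n_replacement.sum())
        sum_s = int(kept.n_silent.sum())
        row = dict(zip(groupby, keys))
        row.update(
            n_reads=len(g),
            n_excluded=int(g.excluded.sum()),
            n_undetermined=int((kept.codon33_class == "Undetermined").sum()),
            n_classified=n_classified,
            frac_W=counts.get("W", 0) / n_classified if n_classified else float("nan"),
            frac_L=counts.get("L", 0) / n_classified if n_classified else float("nan"),
            frac_Other=counts.get("Other", 0) / n_classified if n_classified else float("nan"),
            sum_R=sum_r,
            sum_S=sum_s,
            rs_ratio=sum_r / sum_s if sum_s > 0 else float("nan"),
            rs_defined=sum_s > 0,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.drop(columns=["_all"], errors="ignore")
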