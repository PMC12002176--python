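# Methods

This note documents the models, conventions, and numerical choices
behind each stage of the pipeline, what the synthetic generators do and
do not emulate, and the known limitations.

## Mutation calling against the germline V window

**Model.** Every read is assumed to derive from a single, known,
codon-framed germline V segment (a V_H186.2-style consensus carrying a
tryptophan, TGG, at the key codon — index 33 by default, 1-based and
sequential within the supplied window, not Kabat/IMGT renumbered).
Differences from the germline are attributed to somatic hypermutation.

**Alignment.** Reads are aligned with a global affine-gap aligner
(Bio.Align.PairwiseAligner; match/mismatch/open/extend = 2/−1/−6/−1,
configurable) with free end gaps, so a read that starts or ends inside
the window registers as partial *coverage* rather than as gaps. Codon
pairs are emitted only for reference codons whose three bases are
contiguously aligned. Any internal gap sets `gap_flag` and excludes the
read from mutation counting (reason `frameshift`): replacement/silent
counting presumes an intact frame, and a single indel shifts every
downstream codon. A consequence of free end gaps is that an indel within
~2 nt of either window edge is absorbed into an end gap and reads as
slightly reduced coverage instead — the synthetic generator therefore
places its test indels at least 3 nt inside the window. Reads covering
fewer than 90% of the reference codons, or missing the key codon, are
excluded with reason `low_coverage` (thresholds configurable).

**Codon-33 classes.** The aligned key codon is translated: TGG → `W`;
any of the six leucine codons → `L` (the high-affinity class; the
canonical event is the single-nucleotide TGG→TTG change); any other
amino acid or a stop → `Other`; an N or an uncovered key codon →
`Undetermined`.

**R/S counting.** For each fully covered, N-free codon that differs
from the germline, every mismatching nucleotide is counted, and all
mismatches in the codon inherit the codon-level class: *replacement* iff
the translated amino acids differ, else *silent*. This final-codon
convention (rather than enumerating single-step mutation orders) is the
simplest consistent reading of a per-sequence replacement/silent
quantity; a two-nucleotide TGG→CTG change therefore counts as 2
replacement mutations. Counts are conserved by construction:
n_R + n_S equals the number of mismatching non-ambiguous nucleotides in
N-free covered codons, which the tests verify against an independent
position-wise recount.

**Group summaries.** Class fractions (frac_W/frac_L/frac_Other) are
taken over classified reads only; Undetermined reads are reported
separately but their mutation counts still pool into sum_R/sum_S, since
an ambiguous base at the key codon does not invalidate counts elsewhere.
The R/S ratio is pooled per group (sum_R/sum_S, one value per
mouse/condition), flagged undefined when sum_S = 0; per-read ratios are
available from the per-read table.

**Open choices.** Counting spans the whole supplied window (not
CDR-only), and codon numbering is sequential; both choices are
configurable inputs rather than assertions about any particular
lab pipeline.

## GC geometry and the polarization fraction

Areas and centroids are exact polygon quantities (shapely): shoelace
area independent of vertex orientation, and the area centroid as the
continuous analogue of averaging mask pixels — the two differ only at
sub-pixel scale (the imaging this is designed for has 0.170 µm pixels,
kept as a config default).

The polarization fraction for a cell type: let *c* be the region
centroid and *m* the mean cell coordinate; project each cell onto
*d = m − c* and count cells with positive vs negative projection; the
fraction is max(count)/n. Choices the definition leaves open:

* **Boundary cells** with |projection| ≤ tol (default tol = 0, i.e.
  exact zeros) count half to each side, keeping the statistic symmetric
  and inside [0.5, 1].
* **Degenerate direction** (|d| ≤ tol, or n < 2): reported as 0.5 with a
  `degenerate` flag — "maximally unpolarized" is the conservative
  reading; an error would discard exactly the GCs with no polarity.
* Cells outside the polygon are kept by default (segmentation happens
  inside the ROI upstream, so the case should not arise); `clip=True`
  restricts to the polygon.

The statistic is invariant under rigid motions and has a positive bias
at finite n: for uniformly spread cells the expected fraction is
≈ 0.5 + c/√n (≈ 0.54 at n = 100), decreasing toward 0.5 — the tests
check this null behaviour. Because the splitting direction is
*estimated from the cells*, a fully one-sided pattern measures exactly
1.0 only when the half's centroid lies along the generating axis (true
for a disk; a square region at an oblique cut attenuates the measured
fraction slightly, which the tests demonstrate).

## Clonotype clustering

Cells (one productive heavy and light chain each) are joined when the
normalized Hamming similarity of *both* junction pairs reaches the
threshold (default 0.85); clones are single-linkage connected
components, per mouse. Conventions: unequal-length junctions never
match (Hamming distance is undefined across lengths, and indel-bearing
junction variants are rare enough to ignore); comparison is
case-insensitive; N mismatches every base including another N; V/J gene
agreement is optional (`require_same_vj`) since junction identity at
85% already implies near-identical rearrangements. Complete linkage and
an OR-of-chains rule exist behind flags. Clone ids are deterministic
(size-descending, then lexicographically smallest member).

Expansion and sharing statistics follow the study design: a clone is
*expanded* when it has ≥3 GC-compartment members (memory cells do not
count toward expansion); the per-mouse Venn partitions GC clones by the
tissues of their GC members; the sharing matrix gives, for each source
tissue *t* and target tissue *u*, the percentage of clones with a GC
member in *t* that also have ≥1 MBC member in *u*.

## Synthetic data: what it emulates, what it does not

* **Reads** (`simulate_shm_reads`): i.i.d. per-base substitutions at
  rate µ (uniform over the three alternatives — no AID hotspot bias, no
  transition/transversion skew, since the analyses do not model
  mutation bias), an optional forced TGG→TTG change with probability
  p_w33l, at most one internal 1-nt indel per read, and i.i.d. N
  masking. N masking is applied before the indel so the recorded truth
  (R/S counts under the final-codon convention, key-codon class) is
  consistent with the pipeline on every frame-intact read by
  construction. Not emulated: chromatogram noise structure, PCR errors,
  clonal phylogeny among reads — so passing tests show correct counting
  and classification, not robustness to base-calling artifacts.
* **Point patterns** (`simulate_gc_sample`): a random half of the
  region through its centroid receives probability mass π ∈ [0.5, 1],
  cells uniform within their half. Real GC cell patterns have density
  gradients and exclusion zones this ignores; the generator is designed
  to make the polarization parameter identifiable, not to render
  histology.
* **Repertoires** (`simulate_repertoire`): founder junction pairs per
  clone (equal-length founders rejection-sampled to < 70% pairwise
  identity; unequal lengths never match by definition), clone sizes
  1 + Poisson, members carrying the founders mutated at exactly
  round(div × length) positions — the count is fixed at its expectation
  so within-clone pairwise divergence is bounded by 2·div and clone
  recovery is a deterministic property of the configuration, not a
  coin flip. Tissue and compartment are drawn i.i.d. per member; clones
  with a *home* tissue are produced by composing calls with skewed
  tissue probabilities (see `analysis/01_simulate.py`). Not emulated:
  V(D)J recombination statistics, SHM lineage structure within clones,
  transcriptomes.

All generators take explicit seeds (numpy default_rng; no global
state) and are deterministic under them.

## Problem sizes and defaults

Defaults used by the drivers and tests: 297-nt window (99 codons, key
codon 33); µ = 0.01 per base and 120 reads per condition in the study
emulation; W33L forcing 0.18/0.67 (early lung/node) and 0.59/0.54
(late), matching the delayed-lung-affinity narrative; 12 GCs with
node radii 80–120 µm vs lung 30–55 µm and π ∈ [0.7, 0.95]; 2 mice × 60
clones at 5% within-clone divergence with 0.75/0.25 GC/MBC assignment.
Verification sizes (500–1000 reads, 1000 point sets, 200-cell oracle
instances, 50 random polygons with 1.5×10⁵ Monte-Carlo points each)
keep the full suite under a minute while leaving the stochastic checks
well inside 3σ bands.

## Known limitations

* The aligner assumes one contiguous amplicon per read; chimeric reads
  are not detected beyond their gap/coverage signature.
* The polarization fraction is a single-axis statistic: a ring-shaped
  or multi-lobed distribution can measure as unpolarized.
* Per-nucleotide (rather than per-codon) classification of multi-hit
  codons, CDR-restricted counting, and Kabat numbering are not
  implemented; the conventions above are applied uniformly.
* Complete-linkage clone assignment is greedy (largest-clique-first)
  and is provided for comparison, not as a reference method.
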