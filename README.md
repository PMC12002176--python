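# ectopicgc

Tools for comparing **ectopic (lung) germinal centers** with conventional
lymph-node germinal centers along three axes:

1. **Affinity maturation from Sanger reads** (`ectopicgc.shm`) — align
   reads from sorted GC B cells to a codon-framed germline V_H186.2-style
   reference, classify the affinity-critical codon 33 (germline tryptophan;
   the W33L leucine substitution confers ~10-fold higher affinity for the
   NP hapten), and count replacement (R) and silent (S) nucleotide
   mutations per read and pooled per group.
2. **GC geometry and polarization** (`ectopicgc.spatial`) — from a GC
   region polygon (CD95 mask, µm) and typed cell coordinates, compute GC
   area, cell density, and the *polarization fraction*: with region
   centroid *c* and cell-type centroid *m*, split the cells by the line
   through *c* perpendicular to *d = m − c* and report
   max(side counts)/*n* ∈ [0.5, 1]. 0.5 means an even spread; 1.0 means
   the cell type is confined to one half of the GC (e.g. the light zone).
3. **Clonotype clustering and sharing** (`ectopicgc.clonotype`) — cluster
   cells by paired heavy/light junctions (normalized Hamming similarity
   ≥ 0.85 on *both* chains, single-linkage components), then compute
   clonal expansions (≥3 GC members), per-mouse lung/mLN Venn counts,
   and the percentage of GC clones re-found in the memory B-cell pool.

A fourth module, `ectopicgc.synthetic`, generates ground-truthed inputs
for all three stages (mutated reads with known substitution positions,
point patterns with a known polarization parameter, repertoires with
known clone labels), so the entire pipeline is testable without any
external data.

## Worked example

Simulate 40 reads at a 1% per-base mutation rate with a 40% chance of
the forced W→L change, then call them:

```sh
ectopicgc simulate shm --n-reads 40 --mu 0.01 --p-w33l 0.4 --seed 7 --out sim/
ectopicgc shm-call --reads sim/reads.fasta --reference sim/reference.fasta --out calls/
```

which prints `wrote calls/profiles.tsv (40 reads)`; the per-group summary
(`calls/group_summary.tsv`) for that seed reads

```
n_reads  n_classified  frac_W  frac_L  frac_Other  sum_R  sum_S  rs_ratio
40       40            0.55    0.45    0.0         100    14     7.14
```

i.e. 45% of reads carry a leucine at codon 33 (the generator forced it
in 40% of reads; random substitutions supply the remainder), and pooling
all 40 reads gives 100 replacement vs 14 silent mutations (R/S ≈ 7.1 —
high because the forced W→L change is itself a replacement).

The analysis drivers chain the same steps into the full study layout —
run them in order from the repository root after installing:

```sh
python analysis/01_simulate.py        # ground-truthed inputs -> results/sim/
python analysis/02_shm_analysis.py    # W33L fractions + R/S per condition
python analysis/03_spatial_analysis.py # GC area / density / polarization
python analysis/04_clonotype_analysis.py # clones, Venn, GC->MBC sharing
```

`02` recovers the generating W33L probabilities per tissue/timepoint
condition, `03` reports lymph-node GCs ~5× larger than lung GCs with the
polarization fraction tracking the generating π to ±0.05, and `04`
recovers the simulated clonal partition exactly (ARI = 1.0) and prints
the per-mouse Venn and sharing matrices.

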