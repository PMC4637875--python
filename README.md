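# mirderep

Analysis pipeline for miRNA-knockout transcriptomics, built around the
miR-150⁻/⁻ CD8⁺ T cell study design: quantify miRNAs from small RNA-seq
by dominant-isoform counting, detect derepression of the knocked-out
miRNA's predicted targets as score-binned fold-change CDF shifts, and
test differentially expressed genes for overlap with immune cell-state
signatures. A seeded synthetic-data generator produces every input the
pipeline consumes, so the full analysis is testable end to end without
any sequencing data.

## Who it is for

Computational biologists analysing knockout-vs-wildtype designs who
want a small, transparent, fully reproducible implementation of three
standard analyses:

1. **Small RNA quantification.** Reads are filtered in a fixed
   precedence order — sequencer QC flag, missing 3′ adapter
   (`TGGAAT`), insert < 15 nt after trimming, ambiguous base in the
   trimmed insert — then matched exactly to hairpin references. Within
   each hairpin, reads are grouped by their (start, end) footprint
   (isomiRs) and the dominant isoform's count is used downstream.
2. **Target derepression.** Per-gene log2(KO/WT) fold changes are
   computed from replicate means; predicted targets (TargetScan-style
   context+ scores, more negative = stronger) are split into strength
   bins and each bin's fold-change CDF is compared against the
   background of other conserved miRNAs' targets with a two-sided
   two-sample Kolmogorov–Smirnov test. Genuine direct targeting shows
   up as shifts that grow monotonically with predicted strength.
3. **Signature enrichment.** Genes significant at FDR ≤ 0.05 are split
   into up/down sets and tested against gene signatures (e.g. naïve /
   effector / memory CD8⁺ T cell sets) with a one-sided Fisher exact
   test: p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n) for overlap k, signature
   size K, query size n, universe N.

The KS test, hypergeometric tail, Pearson correlation and
Benjamini–Hochberg q-values are implemented in `mirderep.stats` with
exact modes and log-space arithmetic, and are cross-checked in the test
suite against brute-force enumeration, exact rational arithmetic, and
independent library implementations.

## Worked example

Generate a synthetic bundle mimicking the study (miR-150 at ~70% of
miRNA reads; targets derepressed in proportion to site strength;
signatures planted so the up-set matches naïve/memory-like sets and the
down-set an effector-like set) and run all three stages:

```bash
mirderep demo --out demo --seed 42
```

`demo/results/quant/composition.tsv` then starts:

```
mirna         dominant_count  fraction
mmu-miR-150   13627           0.7014
mmu-miR-16    1558            0.0802
mmu-miR-21    1199            0.0617
...
```

i.e. the knocked-out miRNA dominates the library at the planted 70%.
`demo/results/derepress/derepression.json` reports, per strength bin
(weakest → strongest), the median log2 fold-change shift against
background and its KS p-value:

```
[-0.2, -0.1]   n=1264  shift=0.134  p=8.9e-101
[-0.3, -0.2)   n=452   shift=0.243  p=3.7e-138
(-inf, -0.3)   n=280   shift=0.394  p=3.0e-156
```

— stronger predicted targets are more derepressed, and the monotone
flag in the JSON is true. `demo/results/enrich/enrichment.tsv` shows
the planted directions: the up-set enriches the naïve and memory
signatures (p ≈ 6·10⁻⁸ each) and the down-set the effector signature
(p ≈ 2·10⁻⁷), with 977 genes significant at FDR 5% (502 up, 475 down).

Each stage is also available standalone (`mirderep quant`,
`mirderep derepress`, `mirderep enrich`, `mirderep run --config ...`);
see `mirderep --help`.

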