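# Methods

## Small RNA read model and filtering

A small RNA sequencing read from a TruSeq-style library is modelled as
`insert + adapter + filler`, truncated to the read length (default
50 nt): the insert is the mature miRNA, the adapter is the literal 3′
linker `TGGAAT`, and the filler is sequencing past the linker. Reads
are filtered with exactly one outcome each, in a fixed precedence
order: sequencer QC failure (the CASAVA "is filtered" flag, `Y` in the
header comment), no adapter occurrence, insert shorter than `min_len`
(default 15 nt) after trimming at the leftmost adapter occurrence, or
an ambiguous base inside the trimmed insert. The precedence makes the
per-reason counts of the filter report well defined and exactly
testable; the report enforces the conservation invariant
`n_input = n_qc_fail + n_no_adapter + n_too_short + n_ambiguous + n_pass`.

Adapter matching is exact. Error-tolerant adapter detection would
change absent/present calls on a handful of reads but makes the planted
ground truth ambiguous; it is deliberately out of scope.

## Hairpin matching and dominant-isoform quantification

Clean inserts are matched to hairpin reference sequences by exact
substring search (a `max_mismatches=1` naive scan is available but off
by default). An insert matching exactly one hairpin is assigned the
footprint `[start, start+len)` at the leftmost occurrence; inserts
matching several hairpins are excluded and reported as
ambiguous-mapping rather than fractionally assigned, keeping counts
deterministic. No genome pre-filter is applied: with exact matching
against the hairpin set, a genome screen upstream would only remove
reads that already fail to match any hairpin.

Within a hairpin, reads are grouped by footprint — isomiRs — and the
**dominant isoform** is the footprint with the most reads, ties broken
to the smaller start and then the larger end. The dominant isoform is
keyed by *both* ends; a 5′-only keying would merge 3′-trimmed variants
into one isoform, and the both-ends choice is the stricter, more
reproducible reading. Composition tables normalise dominant-isoform
counts across hairpins and report up to the top 10 miRNAs holding at
least 1% each, with the remainder as "other"; the threshold is applied
per sample. Cross-sample concordance is the Pearson correlation of
log2(dominant count + 1) over shared miRNAs, excluding named miRNAs
(the knocked-out one, whose ablation would otherwise dominate the
correlation).

## Derepression analysis

Per-gene fold change is `log2((mean_KO + ε) / (mean_WT + ε))` over
replicate means, with pseudocount ε = 0.1 abundance units (bounds the
fold change of dropout genes; with ε = 0, zero-mean genes are dropped
with a warning instead of producing non-finite values). Genes whose
pooled mean abundance is below `min_expression = 1` are excluded — the
"expressed" floor. Some floor is required; the value is explicit and
configurable rather than inferred. Mean-based fold changes were chosen
over model-based estimates: they are the ε→0-continuous, assumption-free
summary of the replicate design, and the DE table consumed by the
enrichment stage is an explicit input, not derived from them.

Predicted targets of the knocked-out miRNA are genes whose best (most
negative) context+ score is at or below a threshold; both target and
background selection use the boundary-inclusive convention (≤). The
background is every gene with a qualifying score for any *other*
conserved miRNA, minus genes that also qualify for the knocked-out
miRNA. For the binned analysis, targets are selected at the weakest
bin edge (−0.1) so the weak bin is populated; the single-set "target"
definition defaults to the stricter −0.2.

Score bins are `[lower, upper)` — closed on the stronger side — with
the strongest stratum strictly below its edge (`score < −0.3`) and the
weakest bin also closing its upper edge so the selection threshold
itself is binned. A boundary score of exactly −0.3 therefore belongs
to `[−0.3, −0.2)`. Defaults: edges (−0.1, −0.2, −0.3), giving bins
[−0.2, −0.1], [−0.3, −0.2), (−∞, −0.3).

Each bin's fold changes are compared to the background by a two-sided
two-sample KS test; the median shift is bin median minus background
median, and the monotone flag records whether shifts are non-decreasing
with bin strength. The background is used at full size — the KS test
handles unequal sample sizes, and down-sampling would discard
information. No multiple-testing correction is applied across the
three bins; each bin's p-value is reported as-is.

## Statistical primitives

**Two-sample KS.** D is the maximum |ECDF difference| evaluated at
every pooled distinct value, so ties are handled consistently. The
p-value is exact — full enumeration of all C(n1+n2, n1) label
assignments of the pooled multiset, tie-aware by construction — when
n1+n2 ≤ 16 in auto mode (C(16,8) = 12,870 splits is instant), and
asymptotic otherwise: the Kolmogorov survival function evaluated at
λ = √(n_e)·D with n_e = n1·n2/(n1+n2), using the theta-function form of
the series for λ < 1 where the alternating series converges slowly.
The uncorrected Smirnov λ was chosen deliberately: finite-sample λ
corrections of the form (√n_e + 0.12 + 0.11/√n_e) approximate the
*mid-p* of the discrete null distribution of D, whereas the plain limit
tracks the inclusive tail P(D ≥ d) that exact and permutation p-values
use — in permutation experiments at n1 = n2 = 100 the plain form agrees
with a 10⁵-replicate permutation estimate to within ~0.003 at
on-lattice D values, while the corrected form deviates by up to ~0.02.
Asymptotic p-values remain approximate under heavy ties; the result
object records which method produced it.

**One-sided Fisher exact.** The upper hypergeometric tail is computed
in log-space via log-gamma with a reverse log-sum-exp accumulation, so
genome-scale universes (N ≈ 20,000) neither overflow nor lose the tail.
The test suite sweeps every table with N ≤ 60 against exact integer
arithmetic.

**Benjamini–Hochberg.** Step-up q-values via a reverse cumulative
minimum, clipped at 1, order-preserving with p.

## Enrichment

The universe is the set of all genes tested for differential
expression (not the genome); signature genes outside the universe are
dropped before testing so the 2×2 table is well defined. Up/down sets
are `q ≤ fdr` with strictly positive/negative log2 fold change; zero
fold change stays unassigned. The star flag at p < 10⁻¹⁰ is a display
convention carried in the output, not a correction procedure; no
adjustment is applied across the 2 × |signatures| cells.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
validated.

*Reads.* Hairpins are random sequences (≥ 40 nt) that avoid the adapter
substring, so trimming cannot truncate a genuine insert. Clean inserts
start at a fixed hairpin offset (10) with length drawn from
`insert_len_range` (default (22, 22), so every clean read is the single
dominant isoform and truth-count equalities are exact; widening the
range produces isomiR structure with varying 3′ ends). Planted failure
reads carry exactly one failure reason each — QC-flagged but otherwise
well formed, adapter-free by rejection sampling, short-insert (1–14 nt),
or one N inside the insert — so the filter's per-reason counts have
exact ground truth. Per-hairpin clean counts are multinomial in the
configured composition.

*Expression.* WT replicates are 2^(baseline + noise) and KO replicates
2^(baseline + true_lfc + noise), with baseline ~ N(5, 2²) on the log2
scale and i.i.d. N(0, noise_sd²) replicate noise (log-normal noise is
the simplest model under which the log2 fold change of means is
unbiased for small noise; default noise_sd 0.25). Targets (default 20%
of genes, echoing ~2,000 expressed predicted targets in a ~10,000-gene
expressed universe) receive true_lfc = β·|score| with β = 1 by default;
scores are −(0.1 + Exp(0.1)), placing every target at or below the
weakest bin edge with a strong-target tail. A further 30% of genes are
background — scored targets of other conserved miRNAs with no planted
effect. Optional indirect effects (±0.8 log2 units on unscored genes,
off by default, enabled in the demo at n/25 up and n/20 down) emulate
the downstream network of a knockout and give the demo a realistic
down-regulated DE set.

*DE table and signatures.* The DE fixture applies a Welch t-test on
log2 values per gene with BH correction — deliberately simple stand-in
machinery, not a reimplementation of any particular DE method. The
signature generator plants an overlap of `enrichment × K·n/N` genes
between a signature and its designated query set, drawing the rest
outside it; at enrichment 1 it reduces to uniform sampling, and the
three signatures are disjoint by default.

What the generator does **not** emulate: sequencing quality score
variation, adapter sequencing errors, multi-mapping reads between
homologous hairpins, count overdispersion beyond log-normal noise,
correlated genes, library-size effects, or real signature curation.
Passing tests therefore demonstrate correctness of the algorithms under
a clean, known-truth model — not robustness to every artefact of real
libraries.

## Problem sizes and tolerances used in validation

The test and acceptance runs use: 1,000-read libraries for exact filter
counts; 50,000 reads for composition recovery (±0.02 at a planted 70%,
vs a 3σ multinomial bound of ±0.006 — slack covers filter losses);
10,000 genes, 6 replicates/arm for parameter recovery (per-bin median
shift within ±0.05 of β·mean|score|; the dominant error term is the
mean-vs-median gap of the skewed within-bin score distribution, damped
by noise convolution); 500 replicates at 10,000 genes, 3 replicates/arm
for null calibration (per-bin KS rejection at α = 0.05 within 5% ± 2%;
the smallest bin holds ~260 genes, large enough for the asymptotic
approximation). Exact-KS enumeration is validated for pooled sizes
≤ 12 against independent enumeration, and the hypergeometric tail
exhaustively for N ≤ 60.

## Known limitations

- Exact substring matching (0–1 mismatches) against hairpins is a
  deliberate simplification of aligner-based quantification; it
  underestimates counts for reads with >1 error and cannot resolve
  multi-mapping reads.
- Asymptotic KS p-values under heavily tied fold-change vectors are
  approximate; exact mode is limited to small pooled sizes.
- The expression model is log-normal with gene-independent noise;
  count-based overdispersion and mean–variance coupling are not
  modelled, so DE fixture q-values should not be treated as a DE-method
  benchmark.
- Real signature gene lists are external inputs; the planted
  signatures validate the machinery and the direction logic only.
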