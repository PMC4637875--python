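"""Synthetic-data generators for every input the pipeline consumes.

Two generators carry the scientific structure:

* ``gen_smallrna_fastq`` emulates a TruSeq-style small RNA library:
  each clean read is a mature-miRNA insert (a fixed-coordinate hairpin
  substring, so a dominant isoform exists) followed by the 3' adapter
  and random filler, with exactly the configured numbers of planted
  QC-failed, adapter-less, short-insert and ambiguous-base reads. Each
  planted bad read has exactly one failure reason, so the filter's
  per-reason counts have exact ground truth.

* ``gen_expression`` emulates paired wild-type / knockout expression in
  which predicted targets of the knocked-out miRNA are derepressed in
  proportion to their predicted site strength: a target gene with
  context+ score s gains ``beta * |s|`` log2 units in the knockout arm,
  on top of log-normal replicate noise (normal on the log2 scale).
  "Background" genes are targets of other conserved miRNAs with no
  planted effect; optional indirect up/down effects on non-target genes
  emulate the downstream transcriptional network of a knockout.

Everything is driven by a single integer seed per generator and is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_qvalues
from .quant import SmallRNARead, IsoformKey

__all__ = [
    "ReadSimConfig",
    "ScoreDistribution",
    "ExprSimConfig",
    "TruthCounts",
    "SimulatedExpression",
    "gen_hairpins",
    "gen_smallrna_fastq",
    "gen_expression",
    "gen_de_table",
    "gen_signatures",
    "write_fastq",
    "write_fasta",
    "write_gmt",
]

_BASES = np.array(list("ACGT"))

OTHER_MIRNAS = ("mmu-miR-16", "mmu-miR-21", "mmu-miR-142", "mmu-let-7a",
                "mmu-miR-29a", "mmu-miR-155")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class ReadSimConfig:
    """Configuration for the small RNA read simulator.

    ``composition`` maps hairpin names to clean-read fractions (sums to
    1). ``insert_len_range`` is the inclusive range of clean insert
    lengths; the insert always starts at ``mature_start`` on the
    hairpin, so with the default (22, 22) every clean read carries the
    single dominant isoform, and widening the range creates isomiR
    structure (varying 3' ends).
    """

    n_reads: int
    composition: dict[str, float]
    adapter: str = "TGGAAT"
    read_len: int = 50
    mature_start: int = 10
    insert_len_range: tuple[int, int] = (22, 22)
    n_qc_fail: int = 0
    n_no_adapter: int = 0
    n_short_insert: int = 0
    n_ambiguous: int = 0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        lo, hi = self.insert_len_range
        if lo < 1 or hi < lo:
            raise ValueError("insert_len_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must be in [0, 1)")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        planted = (self.n_qc_fail + self.n_no_adapter
                   + self.n_short_insert + self.n_ambiguous)
        if min(self.n_qc_fail, self.n_no_adapter, self.n_short_insert,
               self.n_ambiguous) < 0:
            raise ValueError("planted failure counts must be >= 0")
        if planted > self.n_reads:
            raise ValueError("planted failure counts exceed n_reads")

    @property
    def n_clean(self) -> int:
        return self.n_reads - (self.n_qc_fail + self.n_no_adapter
                               + self.n_short_insert + self.n_ambiguous)


@dataclass
class TruthCounts:
    """Ground truth bookkeeping for a simulated library."""

    n_qc_fail: int
    n_no_adapter: int
    n_short_insert: int
    n_ambiguous: int
    n_clean: int
    clean_counts: dict[str, int]
    dominant_counts: dict[str, int]
    dominant_isoform: dict[str, tuple[int, int]]


def gen_hairpins(
    n: int,
    length: int = 72,
    seed: int = 0,
    names: Sequence[str] | None = None,
    forbid: Sequence[str] = ("TGGAAT",),
) -> dict[str, str]:
    """Generate ``n`` uniquely named random hairpin reference sequences.

    Sequences avoid the forbidden substrings (by default the 3' adapter,
    so that adapter trimming cannot truncate a genuine insert) and are
    pairwise distinct; deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 40:
        raise ValueError("hairpin length must be >= 40")
    if names is not None and len(names) != n:
        raise ValueError("names must have length n")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = _random_dna(rng, length)
        if s in seen or any(f in s for f in forbid):
            continue
        seen.add(s)
        seqs.append(s)
    if names is None:
        names = [f"hairpin-{i + 1:03d}" for i in range(n)]
    if len(set(names)) != n:
        raise ValueError("hairpin names must be unique")
    return dict(zip(names, seqs))


def _dominant_from_counts(counts: dict[tuple[int, int], int]) -> tuple[tuple[int, int], int]:
    return max(counts.items(), key=lambda kv: (kv[1], -kv[0][0], kv[0][1]))


def gen_smallrna_fastq(
    cfg: ReadSimConfig,
    hairpins: Mapping[str, str],
) -> tuple[list[SmallRNARead], TruthCounts]:
    """Simulate a small RNA library with planted, disjoint failure modes.

    Clean reads: hairpin insert + adapter + random filler, truncated to
    ``read_len``. Planted failures (one reason each, in the filter's
    precedence order): QC-flagged reads that are otherwise well-formed;
    adapter-less random reads; short-insert reads (<15 nt before the
    adapter); ambiguous reads with one N inside the insert.
    """
    unknown = set(cfg.composition) - set(hairpins)
    if unknown:
        raise ValueError(f"composition names not in hairpin set: {sorted(unknown)}")
    for name in cfg.composition:
        lo, hi = cfg.insert_len_range
        if cfg.mature_start + hi > len(hairpins[name]):
            raise ValueError(f"hairpin {name} too short for mature insert window")

    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.composition)
    probs = np.array([cfg.composition[n] for n in names], dtype=float)
    lo, hi = cfg.insert_len_range

    def clean_sequence(hp_name: str, record_truth: bool) -> str:
        L = int(rng.integers(lo, hi + 1))
        hp = hairpins[hp_name]
        insert = hp[cfg.mature_start:cfg.mature_start + L]
        if cfg.seq_error_rate > 0:
            bases = list(insert)
            for i in range(len(bases)):
                if rng.random() < cfg.seq_error_rate:
                    bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
            insert = "".join(bases)
        if record_truth:
            key = (cfg.mature_start, cfg.mature_start + L)
            isoform_counts[hp_name][key] = isoform_counts[hp_name].get(key, 0) + 1
        tail_len = cfg.read_len - len(insert) - len(cfg.adapter)
        seq = insert + cfg.adapter + (_random_dna(rng, tail_len) if tail_len > 0 else "")
        return seq[:cfg.read_len]

    if (cfg.n_clean > 0 or cfg.n_ambiguous > 0) and lo < 15:
        raise ValueError("insert_len_range minimum must be >= 15 so planted "
                         "clean/ambiguous reads pass the length filter")

    clean_counts: dict[str, int] = {n: 0 for n in names}
    isoform_counts: dict[str, dict[tuple[int, int], int]] = {n: {} for n in names}

    draws = rng.multinomial(cfg.n_clean, probs)
    entries: list[tuple[str, bool]] = []  # (sequence, qc_fail)

    for name, k in zip(names, draws):
        clean_counts[name] = int(k)
        for _ in range(int(k)):
            entries.append((clean_sequence(name, record_truth=True), False))

    # QC-failed reads: structurally valid, flagged "Y"; excluded from truth
    for _ in range(cfg.n_qc_fail):
        name = names[int(rng.choice(len(names), p=probs))]
        entries.append((clean_sequence(name, record_truth=False), True))

    # adapter-less reads: random sequence guaranteed not to contain the adapter
    for _ in range(cfg.n_no_adapter):
        while True:
            s = _random_dna(rng, cfg.read_len)
            if cfg.adapter not in s:
                break
        entries.append((s, False))

    # short-insert reads: < 15 nt before the adapter
    for _ in range(cfg.n_short_insert):
        L = int(rng.integers(1, 15))
        while True:
            insert = _random_dna(rng, L)
            if cfg.adapter not in insert:
                break
        tail_len = cfg.read_len - L - len(cfg.adapter)
        s = (insert + cfg.adapter + (_random_dna(rng, tail_len) if tail_len > 0 else ""))
        entries.append((s[:cfg.read_len], False))

    # ambiguous reads: one N planted inside an otherwise clean insert
    for _ in range(cfg.n_ambiguous):
        name = names[int(rng.choice(len(names), p=probs))]
        seq = clean_sequence(name, record_truth=False)
        pos = int(rng.integers(0, lo))
        seq = seq[:pos] + "N" + seq[pos + 1:]
        entries.append((seq, False))

    order = rng.permutation(len(entries))
    reads = [
        SmallRNARead(
            id=f"r{i + 1:06d}",
            sequence=entries[j][0],
            quality="I" * len(entries[j][0]),
            qc_fail=entries[j][1],
        )
        for i, j in enumerate(order)
    ]

    dominant_counts: dict[str, int] = {}
    dominant_isoform: dict[str, tuple[int, int]] = {}
    for name in names:
        if isoform_counts[name]:
            key, cnt = _dominant_from_counts(isoform_counts[name])
            dominant_counts[name] = cnt
            dominant_isoform[name] = key
        else:
            dominant_counts[name] = 0

    truth = TruthCounts(
        n_qc_fail=cfg.n_qc_fail,
        n_no_adapter=cfg.n_no_adapter,
        n_short_insert=cfg.n_short_insert,
        n_ambiguous=cfg.n_ambiguous,
        n_clean=cfg.n_clean,
        clean_counts=clean_counts,
        dominant_counts=dominant_counts,
        dominant_isoform=dominant_isoform,
    )
    return reads, truth


@dataclass
class ScoreDistribution:
    """Context+ scores drawn as -(offset + Exponential(scale)).

    offset places every score at or below -offset (the weakest bin edge
    used in the derepression analysis); scale controls how deep the
    strong-target tail reaches.
    """

    offset: float = 0.1
    scale: float = 0.1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return -(self.offset + rng.exponential(self.scale, size=size))


@dataclass
class ExprSimConfig:
    """Configuration for the paired WT/KO expression simulator.

    beta is the derepression coefficient (log2 units gained in the KO
    arm per unit |context+ score|); noise_sd is the per-replicate
    log2-scale noise. frac_background genes are targets of other
    conserved miRNAs (scored, no planted effect) and serve as the
    background set of the derepression analysis. n_indirect_up /
    n_indirect_down plant +/- indirect_lfc effects on unscored genes to
    emulate downstream network effects (default off).
    """

    n_genes: int = 10_000
    n_replicates_per_arm: int = 6
    frac_targets: float = 0.2
    frac_background: float = 0.3
    score_distribution: ScoreDistribution = field(default_factory=ScoreDistribution)
    beta: float = 1.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.25
    target_mirna: str = "mmu-miR-150"
    n_indirect_up: int = 0
    n_indirect_down: int = 0
    indirect_lfc: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_replicates_per_arm < 2:
            raise ValueError("need >= 2 replicates per arm")
        if not (0.0 <= self.frac_targets <= 1.0):
            raise ValueError("frac_targets must be in [0, 1]")
        if not (0.0 <= self.frac_background <= 1.0 - self.frac_targets):
            raise ValueError("frac_background must fit alongside frac_targets")
        n_special = (math.floor(self.frac_targets * self.n_genes)
                     + math.floor(self.frac_background * self.n_genes)
                     + self.n_indirect_up + self.n_indirect_down)
        if n_special > self.n_genes:
            raise ValueError("target/background/indirect gene counts exceed n_genes")


@dataclass
class SimulatedExpression:
    """Expression table, target-score table and planted truth."""

    expr: pd.DataFrame          # genes x samples (abundance scale)
    scores: pd.DataFrame        # gene, mirna, context_score
    truth: pd.DataFrame         # gene, is_target, score, true_lfc, effect
    wt_samples: list[str]
    ko_samples: list[str]


def gen_expression(cfg: ExprSimConfig) -> SimulatedExpression:
    """Simulate paired WT/KO expression with score-proportional
    derepression of the knocked-out miRNA's predicted targets.

    WT replicate values are 2^(baseline + noise); KO replicate values
    are 2^(baseline + true_lfc + noise), with true_lfc = beta * |score|
    for targets and 0 otherwise (plus any configured indirect effects).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = np.array([f"gene{i + 1:05d}" for i in range(n)])

    n_targets = math.floor(cfg.frac_targets * n)
    n_background = math.floor(cfg.frac_background * n)
    perm = rng.permutation(n)
    target_idx = perm[:n_targets]
    background_idx = perm[n_targets:n_targets + n_background]
    rest = perm[n_targets + n_background:]
    up_idx = rest[:cfg.n_indirect_up]
    down_idx = rest[cfg.n_indirect_up:cfg.n_indirect_up + cfg.n_indirect_down]

    target_scores = cfg.score_distribution.sample(rng, n_targets)
    background_scores = cfg.score_distribution.sample(rng, n_background)

    true_lfc = np.zeros(n)
    true_lfc[target_idx] = cfg.beta * np.abs(target_scores)
    true_lfc[up_idx] = cfg.indirect_lfc
    true_lfc[down_idx] = -cfg.indirect_lfc

    effect = np.full(n, "none", dtype=object)
    effect[target_idx] = "direct"
    effect[up_idx] = "indirect_up"
    effect[down_idx] = "indirect_down"

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    r = cfg.n_replicates_per_arm
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, 2 * r))
    log2_expr = baseline[:, None] + noise
    log2_expr[:, r:] += true_lfc[:, None]
    values = np.power(2.0, log2_expr)

    wt_samples = [f"WT_{i + 1}" for i in range(r)]
    ko_samples = [f"KO_{i + 1}" for i in range(r)]
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=wt_samples + ko_samples)

    other = np.array(OTHER_MIRNAS)
    score_rows = pd.DataFrame({
        "gene": np.concatenate([genes[target_idx], genes[background_idx]]),
        "mirna": np.concatenate([
            np.full(n_targets, cfg.target_mirna, dtype=object),
            other[rng.integers(0, len(other), size=n_background)],
        ]),
        "context_score": np.concatenate([target_scores, background_scores]),
    })

    score_col = np.full(n, np.nan)
    score_col[target_idx] = target_scores
    truth = pd.DataFrame({
        "gene": genes,
        "is_target": np.isin(np.arange(n), target_idx),
        "score": score_col,
        "true_lfc": true_lfc,
        "effect": effect,
    })
    return SimulatedExpression(expr=expr, scores=score_rows, truth=truth,
                               wt_samples=wt_samples, ko_samples=ko_samples)


def gen_de_table(
    expr: pd.DataFrame,
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Fixture differential-expression table: per-gene log2FC of arm
    means (with pseudocount), Welch two-sample t-test on log2 values,
    and Benjamini-Hochberg q-values."""
    from scipy import stats as sps

    if len(wt_samples) < 2 or len(ko_samples) < 2:
        raise ValueError("need >= 2 replicates per arm for a t-test")
    wt = expr[list(wt_samples)].to_numpy(dtype=float)
    ko = expr[list(ko_samples)].to_numpy(dtype=float)
    log2fc = np.log2(ko.mean(axis=1) + pseudocount) - np.log2(wt.mean(axis=1) + pseudocount)
    t = sps.ttest_ind(np.log2(ko + pseudocount), np.log2(wt + pseudocount),
                      axis=1, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    q = bh_qvalues(p)
    return pd.DataFrame({"gene": expr.index.to_numpy(), "log2fc": log2fc,
                         "p": p, "q": q})


def gen_signatures(
    universe: Sequence[str],
    designated: Mapping[str, Sequence[str]],
    sizes: Mapping[str, int] | int = 200,
    planted_enrichment: float = 1.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Generate disjoint gene signatures with a planted overlap.

    For each signature, the overlap with its designated query set is
    planted at ``planted_enrichment`` times the uniform expectation
    K*n/N (rounded); the remaining members are drawn outside the query
    set. ``planted_enrichment=1`` reduces to uniform sampling.
    """
    if planted_enrichment < 1.0:
        raise ValueError("planted_enrichment must be >= 1")
    universe = list(dict.fromkeys(universe))
    N = len(universe)
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    out: dict[str, set[str]] = {}
    for name, query in designated.items():
        K = sizes if isinstance(sizes, int) else sizes[name]
        if K > N:
            raise ValueError(f"signature {name}: size {K} exceeds universe {N}")
        query = set(query) & set(universe)
        n = len(query)
        expected = K * n / N
        k_planted = min(int(round(planted_enrichment * expected)), K, n)
        in_pool = sorted(query - used)
        out_pool = sorted((set(universe) - query) - used)
        k_planted = min(k_planted, len(in_pool))
        if K - k_planted > len(out_pool):
            raise ValueError(f"signature {name}: universe exhausted")
        chosen = set(rng.choice(in_pool, size=k_planted, replace=False)) if k_planted else set()
        chosen |= set(rng.choice(out_pool, size=K - k_planted, replace=False))
        used |= chosen
        out[name] = chosen
    return out


# ---------------------------------------------------------------------------
# plain-text writers


def write_fastq(reads: Sequence[SmallRNARead], path) -> None:
    """4-line FASTQ with the QC flag in the CASAVA comment position."""
    with open(path, "w") as fh:
        for r in reads:
            flag = "Y" if r.qc_fail else "N"
            fh.write(f"@{r.id} 1:{flag}:0:SYNTH\n{r.sequence}\n+\n{r.quality}\n")


def write_fasta(hairpins: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in hairpins.items():
            fh.write(f">{name}\n{seq}\n")


def write_gmt(signatures: Mapping[str, Sequence[str]], path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
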