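"""miRNA-target derepression analysis.

In a miRNA knockout, transcripts carrying predicted target sites for
that miRNA lose its repression and shift upward relative to wild type.
The analysis takes per-gene knockout/wild-type log2 fold changes, splits
predicted targets into bins of predicted site strength (TargetScan
context+ score; more negative = stronger), and compares each bin's
fold-change CDF against the background of other conserved miRNAs'
targets with a two-sided two-sample KS test. A real, direct effect
shows up as CDF shifts that grow monotonically with predicted strength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import KSResult, ks_two_sample

__all__ = [
    "ScoreBin",
    "BinResult",
    "DerepressionResult",
    "DEFAULT_BIN_EDGES",
    "best_scores",
    "compute_log2fc",
    "select_targets",
    "select_background",
    "bin_by_strength",
    "derepression_analysis",
]

DEFAULT_SCORE_THRESHOLD = -0.2
DEFAULT_BIN_EDGES = (-0.1, -0.2, -0.3)


@dataclass(frozen=True)
class ScoreBin:
    """Score interval [lower, upper), closed on the stronger (more
    negative) side; the weakest bin closes its upper edge too so the
    selection threshold itself is binned. A boundary score such as -0.3
    therefore belongs to [-0.3, -0.2), matching the convention that the
    strongest stratum is "score < -0.3" strictly."""

    label: str
    lower: float
    upper: float
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")

    def contains(self, score: float) -> bool:
        if self.upper_inclusive:
            return self.lower <= score <= self.upper
        return self.lower <= score < self.upper


@dataclass
class BinResult:
    bin: ScoreBin
    genes: list[str]
    n: int
    median_shift: float
    mean_abs_score: float
    ks: KSResult
    cdf: pd.DataFrame  # columns: value, ecdf

    def to_dict(self) -> dict:
        return {
            "label": self.bin.label,
            "lower": self.bin.lower,
            "upper": self.bin.upper,
            "n": self.n,
            "median_shift": self.median_shift,
            "mean_abs_score": self.mean_abs_score,
            "ks": self.ks.to_dict(),
        }


@dataclass
class DerepressionResult:
    bins: list[BinResult]          # ordered weakest -> strongest
    background_n: int
    background_median: float
    background_cdf: pd.DataFrame
    monotone: bool
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bins": [b.to_dict() for b in self.bins],
            "background_n": self.background_n,
            "background_median": self.background_median,
            "monotone": self.monotone,
            "metadata": self.metadata,
        }


def best_scores(scores: pd.DataFrame, mirna: str) -> pd.Series:
    """Best (most negative) context+ score per gene for one miRNA."""
    sub = scores.loc[scores["mirna"] == mirna]
    return sub.groupby("gene")["context_score"].min()


def compute_log2fc(
    expr: pd.DataFrame,
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    pseudocount: float = 0.1,
    min_expression: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean KO + eps) / (mean WT + eps)).

    Genes whose pooled mean abundance falls below ``min_expression`` are
    excluded (the "expressed" floor). With a zero pseudocount, genes
    with a zero mean in either arm are dropped with a warning rather
    than producing non-finite values.
    """
    wt_samples, ko_samples = list(wt_samples), list(ko_samples)
    if not wt_samples or not ko_samples:
        raise ValueError("WT and KO sample sets must be non-empty")
    if set(wt_samples) & set(ko_samples):
        raise ValueError("WT and KO sample sets must be disjoint")
    missing = (set(wt_samples) | set(ko_samples)) - set(expr.columns)
    if missing:
        raise ValueError(f"unknown sample names: {sorted(missing)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    wt_mean = expr[wt_samples].mean(axis=1)
    ko_mean = expr[ko_samples].mean(axis=1)
    pooled = expr[wt_samples + ko_samples].mean(axis=1)
    expressed = pooled >= min_expression
    wt_mean, ko_mean = wt_mean[expressed], ko_mean[expressed]
    if pseudocount == 0:
        zero = (wt_mean == 0) | (ko_mean == 0)
        if zero.any():
            warnings.warn(f"dropping {int(zero.sum())} genes with a zero arm "
                          "mean and zero pseudocount")
            wt_mean, ko_mean = wt_mean[~zero], ko_mean[~zero]
    lfc = np.log2(ko_mean + pseudocount) - np.log2(wt_mean + pseudocount)
    lfc.name = "log2fc"
    return lfc


def select_targets(
    scores: pd.DataFrame,
    mirna: str,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> set[str]:
    """Predicted targets: genes whose best context+ score for ``mirna``
    is at or below the threshold (boundary-inclusive)."""
    if threshold >= 0:
        raise ValueError("score threshold must be negative")
    best = best_scores(scores, mirna)
    if best.empty:
        warnings.warn(f"miRNA {mirna!r} absent from score table")
        return set()
    return set(best.index[best <= threshold])


def select_background(
    scores: pd.DataFrame,
    mirna_excluded: str,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> set[str]:
    """Background: genes with a qualifying score for any miRNA other
    than the excluded one, minus genes that also qualify as targets of
    the excluded miRNA."""
    if threshold >= 0:
        raise ValueError("score threshold must be negative")
    other = scores.loc[scores["mirna"] != mirna_excluded]
    qualifying = other.groupby("gene")["context_score"].min()
    background = set(qualifying.index[qualifying <= threshold])
    background -= select_targets(scores, mirna_excluded, threshold)
    if not background:
        raise ValueError("background set is empty; analysis cannot proceed")
    return background


def bin_by_strength(
    targets: set[str],
    scores: pd.DataFrame,
    mirna: str,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[tuple[ScoreBin, set[str]]]:
    """Partition target genes into [lower, upper) score bins, ordered
    weakest to strongest; the last bin is open below, (-inf, edge)."""
    edges = list(edges)
    if any(b >= a for a, b in zip(edges, edges[1:])) or not edges:
        raise ValueError("edges must be strictly decreasing and non-empty")
    bins = [
        ScoreBin(f"[{lo}, {hi})", lo, hi)
        for hi, lo in zip(edges[:-1], edges[1:])
    ]
    if bins:  # the weakest bin also holds the selection threshold itself
        b0 = bins[0]
        bins[0] = ScoreBin(f"[{b0.lower}, {b0.upper}]", b0.lower, b0.upper,
                           upper_inclusive=True)
    bins.append(ScoreBin(f"(-inf, {edges[-1]})", -math.inf, edges[-1]))

    best = best_scores(scores, mirna)
    out: list[tuple[ScoreBin, set[str]]] = [(b, set()) for b in bins]
    n_excluded = 0
    for gene in targets:
        if gene not in best.index:
            n_excluded += 1
            continue
        s = best[gene]
        if s > edges[0]:
            n_excluded += 1
            continue
        for b, members in out:
            if b.contains(s):
                members.add(gene)
                break
    if n_excluded:
        warnings.warn(f"{n_excluded} target genes fell above the weakest bin "
                      "edge (or lacked a score) and were excluded from binning")
    assigned = set().union(*(m for _, m in out))
    assert all(not (m1 & m2) for i, (_, m1) in enumerate(out)
               for _, m2 in out[i + 1:]), "bins overlap"
    assert len(assigned) == sum(len(m) for _, m in out), "bins not disjoint"
    return out


def _ecdf_frame(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(values)
    return pd.DataFrame({"value": v, "ecdf": np.arange(1, v.size + 1) / v.size})


def derepression_analysis(
    lfc: pd.Series,
    bins: Sequence[tuple[ScoreBin, set[str]]],
    background: set[str],
    scores: pd.DataFrame | None = None,
    mirna: str | None = None,
    ks_method: str = "asymptotic",
) -> DerepressionResult:
    """Per-bin CDF comparison of target fold changes against background.

    For each strength bin: two-sided KS of the bin's log2 fold changes
    against the background's, and the median shift (bin median minus
    background median). The monotone flag records whether shifts are
    non-decreasing from the weakest to the strongest bin, the expected
    signature of genuine, dose-dependent derepression.
    """
    bg_genes = sorted(background & set(lfc.index))
    if not bg_genes:
        raise ValueError("background set does not intersect the fold-change vector")
    bg = lfc.loc[bg_genes].to_numpy()
    bg_median = float(np.median(bg))

    best = best_scores(scores, mirna) if scores is not None and mirna else None

    results: list[BinResult] = []
    for b, members in bins:
        genes = sorted(members & set(lfc.index))
        if not genes:
            raise ValueError(f"bin {b.label} does not intersect the fold-change vector")
        vals = lfc.loc[genes].to_numpy()
        ks = ks_two_sample(vals, bg, method=ks_method)
        mean_abs = float(np.abs(best.loc[genes]).mean()) if best is not None else float("nan")
        results.append(BinResult(
            bin=b,
            genes=genes,
            n=len(genes),
            median_shift=float(np.median(vals)) - bg_median,
            mean_abs_score=mean_abs,
            ks=ks,
            cdf=_ecdf_frame(vals),
        ))

    shifts = [r.median_shift for r in results]
    monotone = all(b >= a - 1e-12 for a, b in zip(shifts, shifts[1:]))
    return DerepressionResult(
        bins=results,
        background_n=len(bg_genes),
        background_median=bg_median,
        background_cdf=_ecdf_frame(bg),
        monotone=monotone,
        metadata={
            "ks_method": ks_method,
            "boundary_convention": "[lower, upper) bins, strongest stratum "
                                   "strictly below its edge; selection "
                                   "threshold inclusive",
            "note": "asymptotic KS p-values are approximate under ties",
        },
    )
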