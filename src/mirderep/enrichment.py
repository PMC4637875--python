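"""Differential-expression classification and gene-signature enrichment.

Genes significant at an FDR threshold are split into up- and
down-regulated (knockout relative to wild type) sets, and each set is
tested for overlap with curated cell-state signatures (e.g. naive /
effector / memory CD8+ T cell gene sets) by a one-sided Fisher exact
test within the universe of all genes tested for differential
expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .stats import ContingencyCounts, fisher_one_sided

__all__ = [
    "GeneSignature",
    "EnrichmentResult",
    "STAR_P_THRESHOLD",
    "classify_de",
    "enrich",
    "enrichment_report",
    "read_gmt",
]

# display convention for headline significance in enrichment matrices
STAR_P_THRESHOLD = 1e-10


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    query: str
    signature: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fold: float
    star: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def classify_de(
    de: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[set[str], set[str], set[str]]:
    """Split a DE table (gene, log2fc, q) into up / down / universe.

    up = {q <= fdr, log2fc > 0}; down = {q <= fdr, log2fc < 0}; genes at
    exactly zero fold change stay unassigned. The universe is every
    tested gene.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    for col in ("gene", "log2fc", "q"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    if de["gene"].duplicated().any():
        dupes = de.loc[de["gene"].duplicated(), "gene"].head().tolist()
        raise ValueError(f"duplicate genes in DE table, e.g. {dupes}")
    sig = de["q"] <= fdr
    up = set(de.loc[sig & (de["log2fc"] > 0), "gene"])
    down = set(de.loc[sig & (de["log2fc"] < 0), "gene"])
    universe = set(de["gene"])
    return up, down, universe


def enrich(
    query: set[str],
    signature: GeneSignature,
    universe: set[str],
    query_name: str = "query",
) -> EnrichmentResult:
    """One-sided (upper-tail) Fisher exact test of query/signature
    overlap within the universe. Signature genes outside the universe
    are dropped before testing."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    sig_in = signature.genes & universe
    k = len(query & sig_in)
    K = len(sig_in)
    n = len(query)
    N = len(universe)
    p = fisher_one_sided(ContingencyCounts(k=k, K=K, n=n, N=N)) if K and n else 1.0
    fold = (k / n) / (K / N) if K and n else 0.0
    return EnrichmentResult(
        query=query_name, signature=signature.name,
        k=k, K=K, n=n, N=N, p=p, fold=fold, star=p < STAR_P_THRESHOLD,
    )


def enrichment_report(
    up: set[str],
    down: set[str],
    signatures: Sequence[GeneSignature],
    universe: set[str],
) -> pd.DataFrame:
    """2 x |signatures| enrichment matrix (long form) for the up and
    down DE sets against every signature."""
    rows = []
    for qname, query in (("up", up), ("down", down)):
        for sig in signatures:
            rows.append(enrich(query, sig, universe, query_name=qname).to_dict())
    return pd.DataFrame(rows, columns=["query", "signature", "k", "K", "n", "N",
                                       "p", "fold", "star"])


def read_gmt(path) -> list[GeneSignature]:
    """Read GMT-style signatures: name <tab> description <tab> genes..."""
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, "
                                 "description and at least one gene")
            sigs.append(GeneSignature(parts[0], frozenset(parts[2:])))
    return sigs
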