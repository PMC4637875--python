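"""Small RNA-seq read processing and dominant-isoform miRNA quantification.

Reads from a TruSeq-style small RNA library are an ~22-nt mature miRNA
insert followed by the 3' adapter and filler. Processing is:

1. filter: drop reads that failed the sequencer's QC (CASAVA "Y" flag in
   the header comment), lack the adapter, are shorter than ``min_len``
   after adapter trimming, or contain an ambiguous base in the trimmed
   insert — applied in that precedence order, one reason per read;
2. match: assign each clean insert to a hairpin by exact substring match
   (optionally tolerating one mismatch); multi-hairpin matches are set
   aside as ambiguous-mapping;
3. quantify: within each hairpin, group reads by their (start, end)
   footprint (isomiRs) and keep the dominant isoform's count; profile
   fractions are computed over dominant-isoform counts.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import pearson_r

__all__ = [
    "SmallRNARead",
    "FilterReport",
    "IsoformKey",
    "HairpinQuant",
    "MiRNAProfile",
    "MatchResult",
    "parse_fastq",
    "trim_adapter",
    "filter_reads",
    "match_to_hairpins",
    "dominant_isoform_counts",
    "composition_table",
    "mirna_concordance",
]

DEFAULT_ADAPTER = "TGGAAT"
DEFAULT_MIN_LEN = 15


@dataclass(frozen=True)
class SmallRNARead:
    """One sequencing read; ``qc_fail`` mirrors the Illumina CASAVA
    is-filtered flag ("Y" = failed chastity filter)."""

    id: str
    sequence: str
    quality: str
    qc_fail: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_qc_fail: int
    n_no_adapter: int
    n_too_short: int
    n_ambiguous: int
    n_pass: int

    def __post_init__(self) -> None:
        parts = (self.n_qc_fail + self.n_no_adapter + self.n_too_short
                 + self.n_ambiguous + self.n_pass)
        if parts != self.n_input:
            raise ValueError("filter counts do not sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_qc_fail": self.n_qc_fail,
            "n_no_adapter": self.n_no_adapter,
            "n_too_short": self.n_too_short,
            "n_ambiguous": self.n_ambiguous,
            "n_pass": self.n_pass,
        }


@dataclass(frozen=True, order=True)
class IsoformKey:
    """A read footprint on a hairpin: 0-based, half-open [start, end)."""

    hairpin: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid isoform coordinates [{self.start}, {self.end})")


@dataclass(frozen=True)
class HairpinQuant:
    dominant: IsoformKey
    dominant_count: int
    total_count: int
    n_isoforms: int


@dataclass
class MiRNAProfile:
    """Per-hairpin dominant-isoform quantification.

    ``fractions`` normalises dominant-isoform counts across hairpins, the
    quantity behind "relative amounts of the most abundant miRNAs"
    composition plots.
    """

    hairpins: dict[str, HairpinQuant] = field(default_factory=dict)
    n_ambiguous_mapping: int = 0
    n_unassigned: int = 0

    @property
    def n_mirna_matching(self) -> int:
        return sum(h.total_count for h in self.hairpins.values())

    def dominant_counts(self) -> dict[str, int]:
        return {name: h.dominant_count for name, h in self.hairpins.items()}

    def fractions(self) -> dict[str, float]:
        total = sum(h.dominant_count for h in self.hairpins.values())
        if total == 0:
            return {name: float("nan") for name in self.hairpins}
        return {name: h.dominant_count / total for name, h in self.hairpins.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions()
        rows = [
            {
                "mirna": name,
                "dominant_start": h.dominant.start,
                "dominant_end": h.dominant.end,
                "dominant_count": h.dominant_count,
                "total_count": h.total_count,
                "fraction": fr[name],
            }
            for name, h in self.hairpins.items()
        ]
        df = pd.DataFrame(rows, columns=["mirna", "dominant_start", "dominant_end",
                                         "dominant_count", "total_count", "fraction"])
        return df.sort_values("dominant_count", ascending=False, kind="mergesort",
                              ignore_index=True)


@dataclass
class MatchResult:
    assignments: list[IsoformKey]
    n_ambiguous_mapping: int
    n_unassigned: int


def parse_fastq(path) -> Iterator[SmallRNARead]:
    """Parse a 4-line FASTQ file, reading the CASAVA-style QC flag from
    the header comment (``@id 1:Y:0:INDEX`` -> qc_fail=True).

    Raises ValueError naming the record index on malformed records.
    """
    from Bio import SeqIO

    i = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qc_fail = False
            parts = rec.description.split()
            if len(parts) > 1:
                comment = parts[1].split(":")
                if len(comment) >= 2 and comment[1] in ("Y", "N"):
                    qc_fail = comment[1] == "Y"
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SmallRNARead(rec.id, str(rec.seq).upper(), qual, qc_fail)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near index {i}: {exc}") from exc


def trim_adapter(sequence: str, adapter: str) -> str | None:
    """Return the insert preceding the leftmost adapter occurrence, or
    None when the adapter is absent."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    idx = sequence.find(adapter)
    if idx < 0:
        return None
    return sequence[:idx]


def filter_reads(
    reads: Iterable[SmallRNARead],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[str], FilterReport]:
    """Assign each read exactly one outcome, in precedence order
    qc_fail -> no_adapter -> too_short -> ambiguous -> pass, and return
    the clean (trimmed) inserts plus a conservation-checked report."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n_input = n_qc = n_noad = n_short = n_ambig = 0
    clean: list[str] = []
    for read in reads:
        n_input += 1
        if read.qc_fail:
            n_qc += 1
            continue
        insert = trim_adapter(read.sequence, adapter)
        if insert is None:
            n_noad += 1
            continue
        if len(insert) < min_len:
            n_short += 1
            continue
        if any(b not in "ACGT" for b in insert):
            n_ambig += 1
            continue
        clean.append(insert)
    report = FilterReport(n_input, n_qc, n_noad, n_short, n_ambig, len(clean))
    return clean, report


def _find_leftmost(insert: str, hairpin: str, max_mismatches: int) -> int:
    """Leftmost offset of insert within hairpin allowing up to
    max_mismatches substitutions; -1 when absent."""
    if max_mismatches == 0:
        return hairpin.find(insert)
    L = len(insert)
    for off in range(len(hairpin) - L + 1):
        mm = 0
        window = hairpin[off:off + L]
        for a, b in zip(insert, window):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return off
    return -1


def match_to_hairpins(
    inserts: Sequence[str],
    hairpins: Mapping[str, str],
    max_mismatches: int = 0,
) -> MatchResult:
    """Assign clean inserts to hairpins by (near-)exact substring match.

    An insert is assigned iff it matches exactly one hairpin; its
    footprint is the leftmost match offset. Inserts matching several
    hairpins are tallied as ambiguous-mapping and excluded from
    profiles; inserts matching none are tallied as unassigned.
    """
    if not hairpins:
        raise ValueError("hairpin reference set must be non-empty")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    cache: dict[str, IsoformKey | str] = {}
    assignments: list[IsoformKey] = []
    n_multi = n_none = 0
    for insert in inserts:
        hit = cache.get(insert)
        if hit is None:
            matches = []
            for name, seq in hairpins.items():
                off = _find_leftmost(insert, seq, max_mismatches)
                if off >= 0:
                    matches.append((name, off))
                    if len(matches) > 1:
                        break
            if len(matches) == 1:
                name, off = matches[0]
                hit = IsoformKey(name, off, off + len(insert))
            elif matches:
                hit = "multi"
            else:
                hit = "none"
            cache[insert] = hit
        if isinstance(hit, IsoformKey):
            assignments.append(hit)
        elif hit == "multi":
            n_multi += 1
        else:
            n_none += 1
    return MatchResult(assignments, n_multi, n_none)


def dominant_isoform_counts(
    assignments: Iterable[IsoformKey] | MatchResult,
) -> MiRNAProfile:
    """Collapse per-read isoform assignments into a per-hairpin profile.

    Within a hairpin, the dominant isoform is the (start, end) footprint
    with the highest read count; ties break to the smaller start, then
    the larger end.
    """
    n_multi = n_none = 0
    if isinstance(assignments, MatchResult):
        n_multi = assignments.n_ambiguous_mapping
        n_none = assignments.n_unassigned
        assignments = assignments.assignments
    per_hairpin: dict[str, Counter] = defaultdict(Counter)
    for key in assignments:
        per_hairpin[key.hairpin][(key.start, key.end)] += 1
    quants: dict[str, HairpinQuant] = {}
    for name, counts in per_hairpin.items():
        (start, end), cnt = max(
            counts.items(), key=lambda kv: (kv[1], -kv[0][0], kv[0][1])
        )
        quants[name] = HairpinQuant(
            dominant=IsoformKey(name, start, end),
            dominant_count=cnt,
            total_count=sum(counts.values()),
            n_isoforms=len(counts),
        )
    return MiRNAProfile(hairpins=quants, n_ambiguous_mapping=n_multi,
                        n_unassigned=n_none)


def composition_table(
    profile: MiRNAProfile,
    top_n: int = 10,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Ranked miRNA composition: up to ``top_n`` miRNAs each holding at
    least ``min_fraction`` of the dominant-isoform reads, with the
    remainder aggregated as "other"."""
    if not profile.hairpins:
        warnings.warn("empty miRNA profile: composition table is empty")
        return pd.DataFrame(columns=["mirna", "dominant_count", "fraction"])
    df = profile.to_frame()[["mirna", "dominant_count", "fraction"]]
    kept = df[df["fraction"] >= min_fraction].head(top_n)
    rest = df.drop(kept.index)
    rows = kept
    if not rest.empty:
        other = pd.DataFrame(
            [{"mirna": "other",
              "dominant_count": int(rest["dominant_count"].sum()),
              "fraction": float(rest["fraction"].sum())}]
        )
        rows = pd.concat([kept, other], ignore_index=True)
    return rows.reset_index(drop=True)


def mirna_concordance(
    profile_a: MiRNAProfile,
    profile_b: MiRNAProfile,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> float:
    """Pearson correlation of log2(dominant count + 1) over the miRNAs
    shared by two profiles, excluding named miRNAs (typically the
    knocked-out one)."""
    shared = sorted((set(profile_a.hairpins) & set(profile_b.hairpins)) - set(exclude))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared miRNAs after exclusion, got {len(shared)}")
    a = np.log2(np.array([profile_a.hairpins[m].dominant_count for m in shared]) + 1.0)
    b = np.log2(np.array([profile_b.hairpins[m].dominant_count for m in shared]) + 1.0)
    return pearson_r(a, b)
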