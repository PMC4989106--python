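"""Shared genomic data model.

Coordinates are 0-based, half-open throughout (BED convention). A "cohort"
is one reference genome plus one or more query genomes; every interval in
the package lives on the reference assembly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named reference sequence."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class UCE(GenomicInterval):
    """An ultraconserved element: a reference interval whose sequence is
    exactly present in every genome of the cohort."""

    sequence: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError("UCE sequence length does not match coordinates")


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping (start, end)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


@dataclass
class AnnotationSet:
    """Gene models plus ncRNA intervals and per-exon constitutive flags.

    ``constitutive`` maps an exon key ``(chrom, start, end)`` to True
    (constitutive) or False (alternatively spliced / non-constitutive).
    """

    genes: list[Gene] = field(default_factory=list)
    ncrnas: list[GenomicInterval] = field(default_factory=list)
    constitutive: dict[tuple[str, int, int], bool] = field(default_factory=dict)

    def exons(self) -> list[GenomicInterval]:
        out = []
        seen = set()
        for g in self.genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    key = (g.chrom, s, e)
                    if key not in seen:
                        seen.add(key)
                        out.append(GenomicInterval(g.chrom, s, e))
        return sorted(out)

    def splice_sites(self) -> list[GenomicInterval]:
        """Exon terminal bases adjacent to an intron, as 1-nt intervals."""
        sites = set()
        for g in self.genes:
            for t in g.transcripts:
                if len(t.exons) < 2:
                    continue
                for i, (s, e) in enumerate(t.exons):
                    if i > 0:  # exon start borders the upstream intron
                        sites.add((g.chrom, s, s + 1))
                    if i < len(t.exons) - 1:  # exon end borders the downstream intron
                        sites.add((g.chrom, e - 1, e))
        return sorted(GenomicInterval(c, s, e) for c, s, e in sites)


@dataclass
class PeakSet:
    """ChIP peaks for one factor at one developmental stage."""

    factor: str
    stage: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)


@dataclass
class GenomeCohort:
    """One reference genome plus N query genomes (dicts name -> sequence)."""

    reference: dict[str, str]
    queries: list[dict[str, str]]
    reference_name: str = "reference"
    query_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.queries:
            raise ValueError("a cohort needs at least one query genome")
        if not self.query_names:
            self.query_names = [f"query_{i + 1}" for i in range(len(self.queries))]
        self.reference = {c: s.upper() for c, s in self.reference.items()}
        self.queries = [{c: s.upper() for c, s in q.items()} for q in self.queries]

    @property
    def species(self) -> list[str]:
        return [self.reference_name, *self.query_names]


# ---------------------------------------------------------------------------
# Interval-set helpers (merged, sorted interval lists with bisect lookup)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Collapse intervals into per-chromosome sorted non-overlapping runs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(intervals):
        runs = by_chrom.setdefault(iv.chrom, [])
        if runs and iv.start <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], iv.end))
        else:
            runs.append((iv.start, iv.end))
    return by_chrom


def overlaps_track(merged: dict[str, list[tuple[int, int]]], iv: GenomicInterval) -> bool:
    """True iff ``iv`` shares >= 1 base with any run of the merged track."""
    runs = merged.get(iv.chrom)
    if not runs:
        return False
    starts = [r[0] for r in runs]
    i = bisect.bisect_right(starts, iv.end - 1)
    # candidate runs: the one starting at or before iv.end-1
    for j in (i - 1,):
        if 0 <= j < len(runs) and runs[j][1] > iv.start and runs[j][0] < iv.end:
            return True
    return False


def count_overlapping(
    elements: list[GenomicInterval], track: list[GenomicInterval]
) -> int:
    merged = merge_intervals(track)
    return sum(overlaps_track(merged, e) for e in elements)
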