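"""Alignment-free detection of ultraconserved elements (UCEs).

The method finds every genomic segment of at least ``min_length`` nt whose
sequence is exactly shared by all genomes of a cohort, without computing a
whole-genome alignment:

1. extract all k-mers (default k=50) that occur exactly once in the
   reference genome, counting both strands;
2. keep the seeds whose k-mer has a perfect match (either strand) in every
   query genome;
3. fuse genomically overlapping seeds into maximal candidate intervals;
4. verify that each candidate's full reference sequence is itself present
   in every query genome, bisecting candidates that fail.

Uniqueness in the reference makes each seed an unambiguous genomic address;
universality across queries makes it ultraconserved. Fusion reconstitutes
elements longer than k, and the final verification guards against chimeric
candidates whose seeds match different loci in a query.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field

from .model import UCE, GenomeCohort

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DetectionConfig:
    """Parameters of the seed-and-verify detection.

    k: seed length in nt. min_length: shortest element reported.
    strand_mode: "both" counts reverse-complement occurrences toward
    uniqueness and accepts them as query matches; "forward" restricts both
    checks to the forward strand. Seeds containing N are always excluded.
    """

    k: int = 50
    min_length: int = 50
    strand_mode: str = "both"
    include_chroms: list[str] | None = None
    exclude_chroms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.min_length < self.k:
            raise ValueError("min_length must be >= k")
        if self.strand_mode not in ("both", "forward"):
            raise ValueError("strand_mode must be 'both' or 'forward'")


def _kmer_counts(genome: dict[str, str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def extract_unique_kmers(
    reference: dict[str, str],
    k: int,
    strand_mode: str = "both",
) -> dict[str, list[int]]:
    """Positions (per chromosome) whose k-mer occurs exactly once genome-wide.

    Under strand_mode="both" a k-mer's count is its forward occurrences plus
    occurrences of its reverse complement anywhere; a palindromic k-mer
    therefore counts itself twice and is never unique. Windows containing N
    are excluded.
    """
    if all(len(s) < k for s in reference.values()):
        log.warning("k=%d exceeds every reference sequence; no seeds", k)
        return {c: [] for c in reference}
    counts = _kmer_counts(reference, k)
    out: dict[str, list[int]] = {}
    for chrom, seq in reference.items():
        positions = []
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            total = counts[w]
            if strand_mode == "both":
                total += counts.get(revcomp(w), 0)
            if total == 1:
                positions.append(i)
        out[chrom] = positions
    return out


def is_universal(
    kmer: str, queries: list[dict[str, str]], strand_mode: str = "both"
) -> bool:
    """True iff the sequence occurs exactly (>=1 times) in every query genome,
    on the forward strand or, under strand_mode="both", on either strand."""
    rc = revcomp(kmer) if strand_mode == "both" else None
    for genome in queries:
        found = False
        for seq in genome.values():
            if kmer in seq or (rc is not None and rc in seq):
                found = True
                break
        if not found:
            return False
    return True


def fuse_seeds(positions: list[int], k: int) -> list[tuple[int, int, list[int]]]:
    """Fuse genomically overlapping seed windows into maximal intervals.

    Two seeds at p < q overlap iff q - p <= k - 1. Returns
    (start, end, member seed starts) per fused run; positions must be
    sorted ascending.
    """
    runs: list[tuple[int, int, list[int]]] = []
    for p in positions:
        if runs and p - runs[-1][2][-1] <= k - 1:
            start, _end, members = runs[-1]
            members.append(p)
            runs[-1] = (start, p + k, members)
        else:
            runs.append((p, p + k, [p]))
    return runs


def verify_and_emit(
    candidates: dict[str, list[tuple[int, int, list[int]]]],
    cohort: GenomeCohort,
    config: DetectionConfig,
) -> list[UCE]:
    """Verify fused candidates against every query genome and emit UCEs.

    A candidate whose full reference sequence is not universal is bisected
    at the median seed, each half re-fused and re-verified; verified
    sub-elements of at least min_length are emitted. Unverifiable remainders
    are logged and dropped.
    """
    emitted: list[UCE] = []

    def verify(chrom: str, seq: str, start: int, end: int, seeds: list[int]) -> None:
        if is_universal(seq[start:end], cohort.queries, config.strand_mode):
            if end - start >= config.min_length:
                emitted.append(UCE(chrom, start, end, sequence=seq[start:end]))
            return
        if len(seeds) < 2:
            log.info("dropped unverifiable candidate %s:%d-%d", chrom, start, end)
            return
        mid = len(seeds) // 2
        for half in (seeds[:mid], seeds[mid:]):
            for s, e, members in fuse_seeds(half, config.k):
                verify(chrom, seq, s, e, members)

    for chrom, runs in candidates.items():
        seq = cohort.reference[chrom]
        for start, end, seeds in runs:
            verify(chrom, seq, start, end, seeds)

    emitted.sort()
    return _resolve_overlaps(emitted, config.min_length)


def _resolve_overlaps(uces: list[UCE], min_length: int) -> list[UCE]:
    # Bisected halves of one failed candidate can share their boundary
    # region; trim the later element (a substring of a universal sequence
    # is universal) and drop it if it falls under min_length.
    out: list[UCE] = []
    for u in uces:
        if out and u.chrom == out[-1].chrom and u.start < out[-1].end:
            new_start = out[-1].end
            if u.end - new_start >= min_length:
                off = new_start - u.start
                out.append(UCE(u.chrom, new_start, u.end, sequence=u.sequence[off:]))
            else:
                log.info("dropped overlap remainder %s:%d-%d", u.chrom, u.start, u.end)
        else:
            out.append(u)
    return out


def detect_uces(
    cohort: GenomeCohort, config: DetectionConfig | None = None
) -> tuple[list[UCE], dict]:
    """Run the full seed-and-verify detection; returns (UCEs, manifest).

    Output is sorted by (chrom, start), non-overlapping, and numbered
    uce_1..uce_n. The manifest records parameters and genome checksums.
    """
    config = config or DetectionConfig()
    reference = {
        c: s
        for c, s in cohort.reference.items()
        if (config.include_chroms is None or c in config.include_chroms)
        and c not in config.exclude_chroms
    }

    unique = extract_unique_kmers(reference, config.k, config.strand_mode)

    # Universality filter over seed k-mers via per-query k-mer sets (exact
    # same semantics as substring search, one pass per genome).
    query_sets = []
    for genome in cohort.queries:
        kset: set[str] = set()
        for seq in genome.values():
            for i in range(len(seq) - config.k + 1):
                kset.add(seq[i : i + config.k])
        query_sets.append(kset)

    def seed_universal(w: str) -> bool:
        rc = revcomp(w) if config.strand_mode == "both" else None
        return all(w in ks or (rc is not None and rc in ks) for ks in query_sets)

    candidates: dict[str, list[tuple[int, int, list[int]]]] = {}
    for chrom, positions in unique.items():
        seq = reference[chrom]
        universal = [p for p in positions if seed_universal(seq[p : p + config.k])]
        candidates[chrom] = fuse_seeds(universal, config.k)

    uces = verify_and_emit(candidates, cohort, config)
    uces = [
        UCE(u.chrom, u.start, u.end, f"uce_{i + 1}", u.sequence)
        for i, u in enumerate(uces)
    ]

    manifest = {
        "k": config.k,
        "min_length": config.min_length,
        "strand_mode": config.strand_mode,
        "n_uces": len(uces),
        "genome_checksums": {
            name: _genome_checksum(g)
            for name, g in zip(
                cohort.species, [cohort.reference, *cohort.queries]
            )
        },
    }
    return uces, manifest


def _genome_checksum(genome: dict[str, str]) -> str:
    h = hashlib.sha256()
    for chrom in sorted(genome):
        h.update(chrom.encode())
        h.update(genome[chrom].encode())
    return h.hexdigest()[:16]
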