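"""Shared fixtures and the independent brute-force detection oracle.

The oracle reimplements the UCE definition from scratch with naive string
scanning (find-loops over every window, no k-mer index, no set lookups) so
that it shares no mechanics with ucekit.detect.
"""

from __future__ import annotations

import numpy as np
import pytest

from ucekit.model import GenomeCohort, GenomicInterval

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def naive_count(genome: dict[str, str], word: str) -> int:
    """Overlap-aware occurrence count of `word` over all sequences."""
    total = 0
    for seq in genome.values():
        i = seq.find(word)
        while i != -1:
            total += 1
            i = seq.find(word, i + 1)
    return total


def naive_present(genome: dict[str, str], word: str, both: bool) -> bool:
    w2 = rc(word)
    return any(
        word in seq or (both and w2 in seq) for seq in genome.values()
    )


def oracle_uces(
    cohort: GenomeCohort, k: int = 50, min_length: int = 50, both: bool = True
) -> list[GenomicInterval]:
    """Brute-force set: maximal unions of overlapping unique-universal
    k-mer windows whose full reference sequence occurs in every query."""
    out = []
    for chrom, seq in cohort.reference.items():
        seeds = []
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            count = naive_count(cohort.reference, w)
            if both:
                count += naive_count(cohort.reference, rc(w))
            if count != 1:
                continue
            if all(naive_present(q, w, both) for q in cohort.queries):
                seeds.append(i)
        # group transitively overlapping windows (start gap <= k-1)
        group: list[int] = []
        for p in seeds + [None]:
            if p is not None and (not group or p - group[-1] <= k - 1):
                group.append(p)
                continue
            if group:
                s, e = group[0], group[-1] + k
                if e - s >= min_length and all(
                    naive_present(q, seq[s:e], both) for q in cohort.queries
                ):
                    out.append(GenomicInterval(chrom, s, e))
            group = [p] if p is not None else []
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20160531)


@pytest.fixture
def identity_cohort(rng):
    """Three identical 200-nt genomes (one chromosome)."""
    seq = "".join(rng.choice(list("ACGT"), size=200))
    return GenomeCohort({"chr1": seq}, [{"chr1": seq}, {"chr1": seq}])
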