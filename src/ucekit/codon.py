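"""Synonymous-site census over in-frame codon alignments and the Fisher
exact comparison testing whether the absence of synonymous change in one
exon is explicable by chance, given a baseline alignment evolving under the
same conditions.

The census works on third codon positions only, relative to a designated
reference row: a site is synonymous-capable if at least one alternative
third-position nucleotide encodes the same amino acid (every sense codon
except ATG and TGG), and it carries a synonymous substitution if any
non-reference species differs at the third position with the encoded amino
acid unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import hypergeom

from .simulate import CodonAlignment

log = logging.getLogger(__name__)

_CODE = dict(standard_dna_table.forward_table)  # 61 sense codons
_STOPS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for a sense codon; '*' for a stop codon."""
    if codon in _STOPS:
        return "*"
    try:
        return _CODE[codon]
    except KeyError as exc:
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}") from exc


def is_synonymous_capable(codon: str) -> bool:
    """True iff >= 1 alternative third-position nucleotide is synonymous.

    Under the standard genetic code, ATG (Met) and TGG (Trp) are the only
    sense codons with no synonymous third-position alternative.
    """
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no amino acid")
    return any(
        translate_codon(codon[:2] + b) == aa for b in "ACGT" if b != codon[2]
    )


def synonymous_capable(reference_codons: list[str]) -> tuple[list[bool], int]:
    """Capability mask and count over reference codons; an in-frame stop is
    an error naming its position."""
    mask = []
    for i, codon in enumerate(reference_codons):
        if codon in _STOPS:
            raise ValueError(f"in-frame stop codon {codon} at codon {i + 1}")
        mask.append(is_synonymous_capable(codon))
    return mask, sum(mask)


@dataclass
class SiteCensus:
    """Per-codon third-position census relative to the reference row."""

    capable: list[bool]
    substituted_synonymous: list[bool]
    substituted_nonsynonymous: list[bool]
    excluded_columns: list[int] = field(default_factory=list)

    @property
    def n_capable(self) -> int:
        return sum(self.capable)

    @property
    def n_synonymous_substituted(self) -> int:
        return sum(self.substituted_synonymous)

    @property
    def n_capable_unsubstituted(self) -> int:
        return sum(
            c and not s
            for c, s in zip(self.capable, self.substituted_synonymous)
        )


def census(alignment: CodonAlignment) -> SiteCensus:
    """Third-position substitution census of an in-frame alignment.

    A capable site is substituted_synonymous if >= 1 non-reference species
    differs from the reference at the third position with the amino acid
    preserved; an amino-acid-changing third-position difference sets
    substituted_nonsynonymous instead. First- and second-position
    differences are ignored. Columns with gaps or non-ACGT characters in
    any species are excluded with logging.
    """
    ref_seq = alignment.sequences[alignment.reference]
    if len(ref_seq) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    n_codons = len(ref_seq) // 3
    others = [s for s in alignment.species if s != alignment.reference]

    capable, syn, non = [], [], []
    excluded = []
    for i in range(n_codons):
        sl = slice(3 * i, 3 * i + 3)
        column = [ref_seq[sl]] + [alignment.sequences[sp][sl] for sp in others]
        if any(set(c) - set("ACGT") for c in column):
            log.info("codon column %d excluded (gap or non-ACGT)", i + 1)
            excluded.append(i)
            capable.append(False)
            syn.append(False)
            non.append(False)
            continue
        ref_codon = column[0]
        if ref_codon in _STOPS:
            raise ValueError(f"in-frame stop codon at codon {i + 1}")
        cap = is_synonymous_capable(ref_codon)
        s_flag = n_flag = False
        ref_aa = translate_codon(ref_codon)
        for cod in column[1:]:
            if cod[2] == ref_codon[2]:
                continue
            derived = ref_codon[:2] + cod[2]
            if translate_codon(derived) == ref_aa:
                s_flag = True
            else:
                n_flag = True
        capable.append(cap)
        syn.append(s_flag and cap)
        non.append(n_flag)
    return SiteCensus(capable, syn, non, excluded)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Minimum-likelihood two-sided rule: sum the hypergeometric probabilities
    of every table with the observed margins whose probability does not
    exceed the observed table's probability times (1 + 1e-7), evaluated in
    log space.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        int(x) != x for x in (a, b, c, d)
    ):
        raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        log.warning("empty 2x2 table; Fisher p defined as 1")
        return 1.0
    r1, c1 = a + b, a + c
    dist = hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    logp0 = dist.logpmf(a)
    total = 0.0
    log_cut = logp0 + math.log1p(1e-7)
    for x in range(lo, hi + 1):
        lp = dist.logpmf(x)
        if lp <= log_cut:
            total += math.exp(lp)
    return min(1.0, float(total))


def constraint_test(
    exon_alignment: CodonAlignment, baseline_alignment: CodonAlignment
) -> dict:
    """Fisher exact test of the 2x2 table

        exon:     synonymous-substituted vs capable-unsubstituted sites
        baseline: synonymous-substituted vs capable-unsubstituted sites

    asking whether the exon's lack of synonymous change is explicable by
    the substitution regime observed in the baseline (e.g. a microexon vs
    the homeodomain of the same gene)."""
    if set(exon_alignment.species) != set(baseline_alignment.species):
        raise ValueError("exon and baseline alignments must share species")
    ce, cb = census(exon_alignment), census(baseline_alignment)
    if ce.n_capable == 0 or cb.n_capable == 0:
        return {"table": None, "p": math.nan, "testable": False}
    table = [
        [ce.n_synonymous_substituted, ce.n_capable_unsubstituted],
        [cb.n_synonymous_substituted, cb.n_capable_unsubstituted],
    ]
    return {"table": table, "p": fisher_exact_2x2(table), "testable": True}
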