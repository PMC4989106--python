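"""Overlap-based enrichment statistics.

All tests compare detected elements against the length-matched
uniquely-mapping reference elements: per-factor chi-square scans with
Benjamini-Hochberg correction across the whole factor x class family,
per-element multifunctionality profiles (coding / splice site / RNA
editing / TF binding) with a Mann-Whitney shift test, the 2^4 function-
combination fold table, the alternative-splicing overlap test, and the
exonic-splicing-enhancer motif scan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GenomicInterval, PeakSet, merge_intervals, overlaps_track

ALPHA = 0.05
SCAN_CLASSES = ("intergenic", "intronic", "exonic")


# ---------------------------------------------------------------------------
# Statistical kernels
# ---------------------------------------------------------------------------


def chi_square_2x2(
    table: tuple[int, int, int, int], yates: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (a, b, c, d), optional Yates
    continuity correction (default on). A zero row or column margin makes
    the test undefined: (nan, nan) is returned rather than raising."""
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    if min(a + b, c + d, a + c, b + d) == 0:
        return (math.nan, math.nan)
    stat, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=yates
    )
    return float(stat), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving;
    NaN entries (untestable rows) stay NaN and do not count toward the
    family size."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    For samples of at most 8 per group the p-value is exact: the standard
    exact distribution without ties, full permutation enumeration with ties
    (the U null is symmetric, so this equals the |U - mean| tail sum).
    Larger samples use the normal approximation with tie correction.
    """
    x, y = list(x), list(y)
    if len(x) <= 8 and len(y) <= 8:
        if len(set(x) | set(y)) == len(x) + len(y):
            method = "exact"
        else:
            method = stats.PermutationMethod(
                n_resamples=math.comb(len(x) + len(y), len(x)) + 1
            )
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _direction(fold: float, p_adj: float, alpha: float = ALPHA) -> str:
    if math.isnan(p_adj):
        return "untestable"
    if p_adj < alpha:
        return "enriched" if fold > 1 else "depleted"
    return "ns"


# ---------------------------------------------------------------------------
# Factor scan
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    factor: str
    stage: str
    element_class: str
    a: int  # elements overlapping the track
    b: int  # elements not overlapping
    c: int  # reference elements overlapping
    d: int  # reference elements not overlapping
    fold: float
    chi2: float
    p: float
    p_adj: float
    direction: str


def _overlap_counts(
    elements: list[GenomicInterval], track: list[GenomicInterval]
) -> tuple[int, int]:
    merged = merge_intervals(track)
    a = sum(overlaps_track(merged, e) for e in elements)
    return a, len(elements) - a


def _make_result(factor, stage, cls, a, b, c, d, yates) -> EnrichmentResult:
    chi2, p = chi_square_2x2((a, b, c, d), yates=yates)
    if (a + b) == 0 or (c + d) == 0:
        fold = math.nan
    elif c == 0:
        fold = math.inf if a > 0 else math.nan
    else:
        fold = (a / (a + b)) / (c / (c + d))
    return EnrichmentResult(factor, stage, cls, a, b, c, d, fold, chi2, p, math.nan, "")


def factor_scan(
    elements_by_class: dict[str, list[GenomicInterval]],
    reference_by_class: dict[str, list[GenomicInterval]],
    peak_sets: list[PeakSet],
    yates: bool = True,
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """One 2x2 chi-square per (factor x element class), BH-corrected across
    the whole family jointly. Classes default to intergenic/intronic/exonic;
    ncRNA-overlapping elements are expected to be excluded upstream."""
    results = []
    for ps in peak_sets:
        for cls in SCAN_CLASSES:
            els = elements_by_class.get(cls, [])
            refs = reference_by_class.get(cls, [])
            a, b = _overlap_counts(els, ps.intervals)
            c, d = _overlap_counts(refs, ps.intervals)
            results.append(_make_result(ps.factor, ps.stage, cls, a, b, c, d, yates))
    adj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        r.direction = _direction(r.fold, r.p_adj, alpha)
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.factor, r.stage, r.element_class, r.a, r.b, r.c, r.d,
                r.fold, r.chi2, r.p, r.p_adj, r.direction,
            )
            for r in results
        ],
        columns=[
            "factor", "stage", "class", "a", "b", "c", "d",
            "fold", "chi2", "p", "p_adj", "direction",
        ],
    )


# ---------------------------------------------------------------------------
# Multifunctionality
# ---------------------------------------------------------------------------

FLAGS = ("coding", "splice_site", "editing", "tf_bound")


@dataclass
class FunctionProfile:
    element: GenomicInterval
    coding: bool
    splice_site: bool
    editing: bool
    tf_bound: bool

    @property
    def score(self) -> int:
        return sum((self.coding, self.splice_site, self.editing, self.tf_bound))

    @property
    def combo(self) -> tuple[bool, bool, bool, bool]:
        return (self.coding, self.splice_site, self.editing, self.tf_bound)


def function_profiles(
    elements: list[GenomicInterval],
    coding_intervals: list[GenomicInterval],
    splice_sites: list[GenomicInterval],
    editing_sites: list[GenomicInterval],
    peak_sets: list[PeakSet],
) -> list[FunctionProfile]:
    """Per-element 4-bit profile; each flag is a >=1-base overlap with the
    corresponding track. tf_bound uses the union of all factors' peaks
    (bound by at least one TF)."""
    all_peaks = [iv for ps in peak_sets for iv in ps.intervals]
    tracks = [
        merge_intervals(coding_intervals),
        merge_intervals(splice_sites),
        merge_intervals(editing_sites),
        merge_intervals(all_peaks),
    ]
    return [
        FunctionProfile(e, *(overlaps_track(t, e) for t in tracks))
        for e in elements
    ]


def multifunctionality(
    profiles_elements: list[FunctionProfile],
    profiles_reference: list[FunctionProfile],
) -> dict:
    """Score distributions (0..4 functions per element) and the two-sided
    Mann-Whitney comparison of element vs reference scores."""
    xs = [p.score for p in profiles_elements]
    ys = [p.score for p in profiles_reference]
    u, p = mann_whitney(xs, ys)
    return {
        "element_scores": np.bincount(xs, minlength=5).tolist(),
        "reference_scores": np.bincount(ys, minlength=5).tolist(),
        "mann_whitney_u": u,
        "mann_whitney_p": p,
    }


def combo_fold(
    profiles_elements: list[FunctionProfile],
    profiles_reference: list[FunctionProfile],
) -> pd.DataFrame:
    """Proportion of each of the 16 function combinations among elements and
    reference, and their ratio. A combination absent from the reference but
    present among elements gets an infinite fold (counts give the context)."""
    if not profiles_elements or not profiles_reference:
        raise ValueError("both profile sets must be non-empty")
    rows = []
    n_el, n_ref = len(profiles_elements), len(profiles_reference)
    for combo in itertools.product((False, True), repeat=4):
        ce = sum(p.combo == combo for p in profiles_elements)
        cr = sum(p.combo == combo for p in profiles_reference)
        pe, pr = ce / n_el, cr / n_ref
        if pr > 0:
            fold = pe / pr
        else:
            fold = math.inf if pe > 0 else math.nan
        rows.append((*combo, ce, cr, pe, pr, fold))
    return pd.DataFrame(
        rows,
        columns=[*FLAGS, "n_elements", "n_reference", "prop_elements",
                 "prop_reference", "fold"],
    )


# ---------------------------------------------------------------------------
# Alternative splicing and ESE motifs
# ---------------------------------------------------------------------------


def alt_splicing_test(
    exonic_elements: list[GenomicInterval],
    nonconstitutive_exons: list[GenomicInterval],
    exonic_reference: list[GenomicInterval],
    yates: bool = True,
) -> EnrichmentResult:
    """Do exonic elements overlap alternatively spliced (non-constitutive)
    exons more often than exonic reference elements? An element counts as
    alternatively spliced if it overlaps >= 1 non-constitutive exon."""
    a, b = _overlap_counts(exonic_elements, nonconstitutive_exons)
    c, d = _overlap_counts(exonic_reference, nonconstitutive_exons)
    r = _make_result("alt_splicing", "", "exonic", a, b, c, d, yates)
    r.p_adj = r.p
    r.direction = _direction(r.fold, r.p_adj)
    return r


def ese_motif_scan(
    element_sequences: list[str],
    reference_sequences: list[str],
    motifs: list[str],
    yates: bool = True,
) -> list[EnrichmentResult]:
    """Per-motif exact sense-strand substring counts in element vs reference
    sequences, chi-square per motif, BH across the motif family."""
    results = []
    for motif in motifs:
        if not set(motif) <= set("ACGT"):
            raise ValueError(f"motif {motif!r} is not over ACGT")
        a = sum(motif in s for s in element_sequences)
        c = sum(motif in s for s in reference_sequences)
        results.append(
            _make_result(
                motif, "", "motif",
                a, len(element_sequences) - a,
                c, len(reference_sequences) - c,
                yates,
            )
        )
    adj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        r.direction = _direction(r.fold, r.p_adj)
    return results
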