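"""Genomic context of detected elements: functional classification against
gene models, the length-matched uniquely-mapping reference-element null,
single-linkage clustering, inter-element distance statistics, and the
UCE-density gene ranking used as input to GO-term analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .detect import revcomp
from .model import AnnotationSet, GenomicInterval, Transcript

log = logging.getLogger(__name__)

CLASSES = ("ncRNA", "junction", "exonic", "intronic", "intergenic")


class AnnotationIndex:
    """Interval-tree index over an AnnotationSet for fast classification."""

    def __init__(self, ann: AnnotationSet):
        self.ann = ann
        self.ncrna = _build_tree((g.chrom, g.start, g.end) for g in ann.ncrnas)
        self.gene_spans = _build_tree(
            (g.chrom, *g.span) for g in ann.genes if g.transcripts
        )
        # transcript tree: payload = (gene chrom, Transcript)
        self.transcripts = {}
        for g in ann.genes:
            for t in g.transcripts:
                lo, hi = t.span
                self.transcripts.setdefault(g.chrom, IntervalTree()).addi(
                    lo, hi, t
                )


def _build_tree(triples) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, lo, hi in triples:
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi)
    return trees


def _tree_overlaps(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    t = trees.get(iv.chrom)
    return bool(t and t.overlap(iv.start, iv.end))


def _exon_intron_overlap(t: Transcript, iv: GenomicInterval) -> tuple[bool, bool]:
    """Does iv overlap >=1 exonic base / >=1 intronic base of transcript t?"""
    lo, hi = t.span
    if iv.end <= lo or iv.start >= hi:
        return False, False
    exon_bp = sum(
        max(0, min(iv.end, e) - max(iv.start, s)) for s, e in t.exons
    )
    span_bp = min(iv.end, hi) - max(iv.start, lo)
    return exon_bp > 0, span_bp - exon_bp > 0


def classify(
    interval: GenomicInterval,
    annotations: AnnotationSet | AnnotationIndex,
) -> str:
    """Assign one of ncRNA / junction / exonic / intronic / intergenic.

    Priority: any ncRNA overlap wins; else an element overlapping both
    exonic and intronic bases of one transcript is a junction element; else
    exon overlap makes it exonic; else lying in a gene makes it intronic;
    everything else is intergenic. One qualifying transcript suffices.
    """
    idx = annotations if isinstance(annotations, AnnotationIndex) else AnnotationIndex(
        annotations
    )
    if _tree_overlaps(idx.ncrna, interval):
        return "ncRNA"
    any_exon = False
    ttree = idx.transcripts.get(interval.chrom)
    if ttree is not None:
        for node in ttree.overlap(interval.start, interval.end):
            ex, intr = _exon_intron_overlap(node.data, interval)
            if ex and intr:
                return "junction"
            any_exon = any_exon or ex
    if any_exon:
        return "exonic"
    if _tree_overlaps(idx.gene_spans, interval):
        return "intronic"
    return "intergenic"


def classify_all(
    intervals: list[GenomicInterval], annotations: AnnotationSet
) -> dict[str, list[GenomicInterval]]:
    idx = AnnotationIndex(annotations)
    out: dict[str, list[GenomicInterval]] = {c: [] for c in CLASSES}
    for iv in intervals:
        out[classify(iv, idx)].append(iv)
    return out


# ---------------------------------------------------------------------------
# Length-matched uniquely-mapping reference elements
# ---------------------------------------------------------------------------


def _count_occurrences(genome: dict[str, str], frag: str) -> int:
    """Occurrences of frag on both strands of the genome (overlap-aware)."""
    total = 0
    targets = (frag, revcomp(frag))
    for seq in genome.values():
        for t in targets:
            start = seq.find(t)
            while start != -1:
                total += 1
                if total > 2:
                    return total
                start = seq.find(t, start + 1)
    return total


def generate_reference_elements(
    reference: dict[str, str],
    length_multiset: list[int],
    seed: int,
    unique_only: bool = True,
) -> list[GenomicInterval]:
    """Tile the genome left-to-right into fragments with lengths drawn
    (with replacement) from the element length distribution; discard
    fragments containing N or, with unique_only, fragments whose sequence
    maps to more than one genomic site counting both strands."""
    if not length_multiset:
        raise ValueError("length multiset is empty")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(length_multiset)
    if all(len(s) < lengths.min() for s in reference.values()):
        log.warning("genome shorter than smallest element length; no fragments")
        return []
    out = []
    n = 0
    for chrom in sorted(reference):
        seq = reference[chrom]
        pos = 0
        while True:
            length = int(rng.choice(lengths))
            if pos + length > len(seq):
                break
            frag = seq[pos : pos + length]
            keep = "N" not in frag
            if keep and unique_only:
                keep = _count_occurrences(reference, frag) == 1
            if keep:
                n += 1
                out.append(GenomicInterval(chrom, pos, pos + length, f"ref_{n}"))
            pos += length
    return out


# ---------------------------------------------------------------------------
# Clustering and distances
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    members: list[GenomicInterval]
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)


def cluster_elements(
    elements: list[GenomicInterval],
    gap_threshold: float,
    classes: dict[GenomicInterval, str] | None = None,
) -> list[Cluster]:
    """Single-linkage chaining: consecutive same-chromosome elements whose
    gap (next.start - prev.end) is strictly below the threshold join one
    cluster. Singletons are not clusters."""
    if gap_threshold <= 0:
        return []
    elements = sorted(elements)
    clusters: list[Cluster] = []
    run: list[GenomicInterval] = []

    def flush():
        if len(run) >= 2:
            cc: dict[str, int] = {}
            if classes:
                for m in run:
                    cc[classes[m]] = cc.get(classes[m], 0) + 1
            clusters.append(
                Cluster(run[0].chrom, run[0].start, run[-1].end, list(run), cc)
            )

    for el in elements:
        if run and el.chrom == run[-1].chrom and el.start - run[-1].end < gap_threshold:
            run.append(el)
        else:
            flush()
            run = [el]
    flush()
    return clusters


def _gaps(elements: list[GenomicInterval]) -> np.ndarray:
    elements = sorted(elements)
    gaps = [
        b.start - a.end
        for a, b in zip(elements, elements[1:])
        if a.chrom == b.chrom
    ]
    return np.asarray(gaps, dtype=float)


def distance_stats(
    elements: list[GenomicInterval],
    reference_elements: list[GenomicInterval],
    n_null: int = 100,
    seed: int = 0,
) -> dict:
    """Observed vs expected median inter-element gap.

    The null draws |elements| members from the uniquely-mapping,
    length-matched reference-element set per replicate (so the null keeps
    the element count, the length distribution and the mappability filter)
    and records their consecutive same-chromosome gaps. The expected median
    is the mean of per-replicate medians; the Mann-Whitney test compares
    observed gaps with the pooled null gaps (two-sided, normal
    approximation with tie correction).
    """
    observed = _gaps(elements)
    if observed.size == 0:
        log.warning("fewer than 2 comparable elements; distance stats undefined")
        return {
            "observed_median": float("nan"),
            "expected_median": float("nan"),
            "mann_whitney_p": float("nan"),
            "n_observed_gaps": 0,
        }
    rng = np.random.default_rng(seed)
    ref = np.array(reference_elements, dtype=object)
    medians, pooled = [], []
    k = min(len(elements), len(reference_elements))
    for _ in range(n_null):
        draw = list(rng.choice(ref, size=k, replace=False))
        g = _gaps(draw)
        if g.size:
            medians.append(np.median(g))
            pooled.append(g)
    null = np.concatenate(pooled) if pooled else np.array([])
    if null.size == 0:
        p = float("nan")
    else:
        p = float(
            stats.mannwhitneyu(
                observed, null, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return {
        "observed_median": float(np.median(observed)),
        "expected_median": float(np.mean(medians)) if medians else float("nan"),
        "mann_whitney_p": p,
        "n_observed_gaps": int(observed.size),
    }


# ---------------------------------------------------------------------------
# Gene ranking for GO analysis
# ---------------------------------------------------------------------------


def go_ranking_score(
    annotations: AnnotationSet,
    elements: list[GenomicInterval],
    reference_elements: list[GenomicInterval],
    flank: int = 10_000,
):
    """Rank genes by (elements in gene span +/- flank) / (reference elements
    in the same interval); genes with zero reference elements in their
    window are excluded and logged. Returns a pandas DataFrame sorted by
    descending score, ties broken by gene id."""
    import pandas as pd

    rows = []
    for g in annotations.genes:
        lo, hi = g.span
        window = GenomicInterval(g.chrom, max(0, lo - flank), hi + flank)
        n_el = sum(window.overlaps(e) for e in elements)
        n_ref = sum(window.overlaps(r) for r in reference_elements)
        if n_ref == 0:
            log.info("gene %s excluded from ranking: no reference elements", g.id)
            continue
        rows.append((g.id, n_el, n_ref, n_el / n_ref))
    df = pd.DataFrame(rows, columns=["gene", "n_elements", "n_reference", "score"])
    return df.sort_values(
        ["score", "gene"], ascending=[False, True], ignore_index=True
    )
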