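"""Synthetic genome cohorts, annotation tracks and codon alignments with
known ground truth.

The generator emulates the study design the pipeline targets: a reference
genome plus N query genomes that diverge by i.i.d. per-site substitutions
(a star phylogeny — the detector is tree-agnostic), with planted identical
elements (true UCEs), near-duplicate decoys carrying a controlled number of
mismatches, gene models with exons/introns/ncRNAs, ChIP-like peak tracks
with a tunable placement bias toward planted elements, RNA-editing sites,
and in-frame codon alignments with controlled third-position substitution
regimes.

Every operation takes an explicit integer seed and derives independent
substreams from it, so identical specs give byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AnnotationSet,
    Gene,
    GenomeCohort,
    GenomicInterval,
    PeakSet,
    Transcript,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    """An element planted identically in every genome (a true UCE)."""

    length: int
    chrom: int = 0
    position: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("planted elements must be >= 50 nt")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("explicit plant sequence length mismatch")


@dataclass
class DecoySpec:
    """A UCE-like element that carries mismatches in some query genomes.

    Mismatch positions are spread evenly so no identical run reaches 50 nt
    for decoy lengths below 50 * (n_mismatches + 1). target_species indexes
    query genomes; None means all queries carry the mismatched copy.
    """

    length: int
    chrom: int = 0
    position: int = 0
    n_mismatches: int = 1
    target_species: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_mismatches < 1:
            raise ValueError("a decoy needs >= 1 mismatch")

    def mismatch_offsets(self) -> list[int]:
        m = self.n_mismatches
        return [((i + 1) * self.length) // (m + 1) for i in range(m)]


@dataclass
class CohortSpec:
    n_species: int
    chrom_lengths: list[int]
    background_divergence: float
    planted_elements: list[PlantSpec] = field(default_factory=list)
    decoy_elements: list[DecoySpec] = field(default_factory=list)
    n_segments: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need >= 2 species (reference + >= 1 query)")
        if any(length < 100 for length in self.chrom_lengths):
            raise ValueError("chromosomes must be >= 100 nt")
        if not 0 <= self.background_divergence < 1:
            raise ValueError("background_divergence must be in [0, 1)")
        self._validate_placements()

    def _validate_placements(self) -> None:
        features: list[tuple[int, int, int, str]] = []
        for i, p in enumerate(self.planted_elements):
            features.append((p.chrom, p.position, p.position + p.length, f"plant_{i}"))
        for i, d in enumerate(self.decoy_elements):
            features.append((d.chrom, d.position, d.position + d.length, f"decoy_{i}"))
        for chrom, s, e, name in features:
            if chrom >= len(self.chrom_lengths) or e > self.chrom_lengths[chrom]:
                raise ValueError(f"{name} exceeds chromosome bounds")
        features.sort()
        for a, b in zip(features, features[1:]):
            if a[0] == b[0] and b[1] - a[2] < 50:
                raise ValueError(
                    f"planted features {a[3]} and {b[3]} overlap or are "
                    "separated by < 50 nt"
                )


@dataclass
class GroundTruth:
    """Planted (truly ultraconserved) and decoy intervals on the reference."""

    plants: list[GenomicInterval]
    decoys: list[GenomicInterval]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def simulate_cohort(spec: CohortSpec) -> tuple[GenomeCohort, GroundTruth]:
    """Generate a reference + (n_species - 1) query genomes.

    Query genomes equal the reference with i.i.d. substitutions at
    ``background_divergence`` per site outside planted/decoy regions;
    planted regions are substitution-free everywhere; decoy regions are
    substitution-free except for exactly ``n_mismatches`` planted
    mismatches in each target species.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_ref, rng_sub, rng_mm = (np.random.default_rng(s) for s in ss.spawn(3))

    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    ref_arrays = [_random_seq(rng_ref, n) for n in spec.chrom_lengths]

    for p in spec.planted_elements:
        if p.sequence is not None:
            ref_arrays[p.chrom][p.position : p.position + p.length] = np.frombuffer(
                p.sequence.encode(), dtype="S1"
            )
    for c, s, n in spec.n_segments:
        ref_arrays[c][s : s + n] = np.bytes_(b"N")

    protected = [np.zeros(n, dtype=bool) for n in spec.chrom_lengths]
    for p in spec.planted_elements:
        protected[p.chrom][p.position : p.position + p.length] = True
    for d in spec.decoy_elements:
        protected[d.chrom][d.position : d.position + d.length] = True

    n_queries = spec.n_species - 1
    queries = []
    for qi in range(n_queries):
        genome = {}
        for ci, (name, ref) in enumerate(zip(chrom_names, ref_arrays)):
            q = ref.copy()
            mask = (
                rng_sub.random(len(q)) < spec.background_divergence
            ) & ~protected[ci] & (q != b"N")
            idx = np.flatnonzero(mask)
            if idx.size:
                shift = rng_sub.integers(1, 4, size=idx.size)
                codes = np.searchsorted(_BASES, q[idx])
                q[idx] = _BASES[(codes + shift) % 4]
            genome[name] = q.tobytes().decode()
            # decoy mismatches overwrite last so counts are exact
        queries.append(genome)

    for d in spec.decoy_elements:
        targets = (
            list(range(n_queries)) if d.target_species is None else d.target_species
        )
        for qi in targets:
            name = chrom_names[d.chrom]
            arr = np.frombuffer(queries[qi][name].encode(), dtype="S1").copy()
            for off in d.mismatch_offsets():
                pos = d.position + off
                code = np.searchsorted(_BASES, arr[pos])
                arr[pos] = _BASES[(code + int(rng_mm.integers(1, 4))) % 4]
            queries[qi][name] = arr.tobytes().decode()

    reference = {n: a.tobytes().decode() for n, a in zip(chrom_names, ref_arrays)}
    cohort = GenomeCohort(reference, queries)

    truth = GroundTruth(
        plants=[
            GenomicInterval(
                chrom_names[p.chrom], p.position, p.position + p.length, f"plant_{i + 1}"
            )
            for i, p in enumerate(spec.planted_elements)
        ],
        decoys=[
            GenomicInterval(
                chrom_names[d.chrom], d.position, d.position + d.length, f"decoy_{i + 1}"
            )
            for i, d in enumerate(spec.decoy_elements)
        ],
    )
    return cohort, truth


def random_cohort_spec(
    rng: np.random.Generator,
    chrom_length: int = 3000,
    n_species: int = 4,
    divergence: float = 0.2,
    plant_lengths: tuple[int, ...] = (50, 75, 120),
    with_decoy: bool = True,
) -> CohortSpec:
    """Draw a valid random CohortSpec: plants (and one decoy) at random
    non-overlapping positions separated by >= 50 nt."""
    lengths = list(plant_lengths)
    decoy_len = 80
    needed = lengths + ([decoy_len] if with_decoy else [])
    while True:
        starts = sorted(
            int(rng.integers(0, chrom_length - max(needed)))
            for _ in range(len(needed))
        )
        ivs = list(zip(starts, needed))
        ok = all(
            b_start - (a_start + a_len) >= 50
            for (a_start, a_len), (b_start, _b) in zip(ivs, ivs[1:])
        ) and ivs[-1][0] + ivs[-1][1] <= chrom_length
        if ok:
            break
    plants = [PlantSpec(length=l, chrom=0, position=s) for s, l in ivs[: len(lengths)]]
    decoys = (
        [DecoySpec(length=decoy_len, chrom=0, position=ivs[-1][0], n_mismatches=1)]
        if with_decoy
        else []
    )
    return CohortSpec(
        n_species=n_species,
        chrom_lengths=[chrom_length],
        background_divergence=divergence,
        planted_elements=plants,
        decoy_elements=decoys,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Annotation / peak / editing tracks
# ---------------------------------------------------------------------------


@dataclass
class PeakTrackSpec:
    factor: str
    stage: str = "E0-12h"
    n_peaks: int = 500
    width_range: tuple[int, int] = (100, 300)
    uce_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.uce_bias < 0:
            raise ValueError("uce_bias must be >= 0")


@dataclass
class TrackSpec:
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 6)
    mean_exon_len: int = 200
    mean_intron_len: int = 500
    n_ncrnas: int = 3
    peak_tracks: list[PeakTrackSpec] = field(default_factory=list)
    editing_density: float = 0.001  # sites per exonic nt
    frac_nonconstitutive: float = 0.4
    seed: int = 0


@dataclass
class Tracks:
    annotations: AnnotationSet
    peak_sets: list[PeakSet]
    editing_sites: list[GenomicInterval]


def simulate_tracks(
    cohort: GenomeCohort, spec: TrackSpec, truth: GroundTruth
) -> Tracks:
    """Generate gene models, ncRNAs, per-factor peak tracks and editing sites
    on the cohort's reference coordinates.

    Peak start positions are drawn from a piecewise-constant density with
    weight ``uce_bias`` inside planted elements and 1 elsewhere, so bias 1
    is placement independent of the planted elements and the expected
    overlap fraction at planted elements increases monotonically with the
    bias (see expected_overlap_probability for the exact value).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_gene, rng_peak, rng_edit = (np.random.default_rng(s) for s in ss.spawn(3))
    chrom_lengths = {c: len(s) for c, s in cohort.reference.items()}

    genes, constitutive = _simulate_genes(rng_gene, chrom_lengths, spec)
    ncrnas = _simulate_ncrnas(rng_gene, chrom_lengths, spec.n_ncrnas)
    ann = AnnotationSet(genes, ncrnas, constitutive)

    peak_sets = [
        PeakSet(
            ps.factor,
            ps.stage,
            place_peaks(rng_peak, chrom_lengths, truth.plants, ps),
        )
        for ps in spec.peak_tracks
    ]

    editing = _simulate_editing(rng_edit, ann, spec.editing_density)
    return Tracks(ann, peak_sets, editing)


def _simulate_genes(rng, chrom_lengths, spec):
    genes: list[Gene] = []
    constitutive: dict[tuple[str, int, int], bool] = {}
    chroms = list(chrom_lengths)
    gi = 0
    pos_by_chrom = {c: int(rng.integers(0, 200)) for c in chroms}
    while gi < spec.n_genes:
        placed = False
        for chrom in chroms:
            if gi >= spec.n_genes:
                break
            pos = pos_by_chrom[chrom]
            n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            exons = []
            p = pos
            for e in range(n_ex):
                elen = max(10, int(rng.poisson(spec.mean_exon_len)))
                exons.append((p, p + elen))
                p += elen
                if e < n_ex - 1:
                    p += max(30, int(rng.poisson(spec.mean_intron_len)))
            if p > chrom_lengths[chrom]:
                # clip trailing exons to the chromosome
                exons = [(s, min(e, chrom_lengths[chrom])) for s, e in exons
                         if s < chrom_lengths[chrom] - 10]
                if len(exons) < 1:
                    continue
                log.warning("gene clipped at end of %s", chrom)
            gi += 1
            gid = f"gene_{gi}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, chrom, strand, [Transcript(f"{gid}.t1", exons)]))
            for s, e in exons:
                constitutive[(chrom, s, e)] = rng.random() >= spec.frac_nonconstitutive
            pos_by_chrom[chrom] = p + max(50, int(rng.poisson(spec.mean_intron_len)))
            placed = True
        if not placed:
            log.warning("ran out of genome space after %d genes", gi)
            break
    return genes, constitutive


def _simulate_ncrnas(rng, chrom_lengths, n_ncrnas):
    out = []
    chroms = list(chrom_lengths)
    for i in range(n_ncrnas):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(70, 150))
        if chrom_lengths[chrom] <= length:
            continue
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length, f"ncRNA_{i + 1}"))
    return sorted(out)


def place_peaks(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    plants: list[GenomicInterval],
    spec: PeakTrackSpec,
) -> list[GenomicInterval]:
    """Draw peak intervals with start density uce_bias inside plants."""
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    plant_len_by_chrom = {c: 0 for c in chroms}
    plants_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chroms}
    for p in plants:
        plant_len_by_chrom[p.chrom] += p.length
        plants_by_chrom[p.chrom].append(p)

    b = spec.uce_bias
    weights = np.array(
        [chrom_lengths[c] + (b - 1.0) * plant_len_by_chrom[c] for c in chroms]
    )
    if weights.sum() <= 0:
        return []
    peaks = []
    for i in range(spec.n_peaks):
        ci = int(rng.choice(len(chroms), p=weights / weights.sum()))
        chrom = chroms[ci]
        w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        lp = plant_len_by_chrom[chrom]
        p_in = b * lp / (chrom_lengths[chrom] + (b - 1.0) * lp)
        if lp and rng.random() < p_in:
            offset = int(rng.integers(0, lp))
            start = None
            for pl in plants_by_chrom[chrom]:
                if offset < pl.length:
                    start = pl.start + offset
                    break
                offset -= pl.length
        else:
            # uniform over non-plant starts
            while True:
                start = int(rng.integers(0, chrom_lengths[chrom]))
                if not any(
                    pl.start <= start < pl.end for pl in plants_by_chrom[chrom]
                ):
                    break
        end = min(start + w, chrom_lengths[chrom])
        if end > start:
            peaks.append(GenomicInterval(chrom, start, end, f"{spec.factor}_{i + 1}"))
    return sorted(peaks)


def expected_overlap_probability(
    chrom_lengths: dict[str, int],
    plants: list[GenomicInterval],
    spec: PeakTrackSpec,
    interval: GenomicInterval,
) -> float:
    """Exact probability that one peak drawn by place_peaks overlaps
    ``interval``: integral of the start-position density over starts in
    [interval.start - width + 1, interval.end), averaged over widths."""
    b = spec.uce_bias
    plant_runs = {
        c: [(p.start, p.end) for p in plants if p.chrom == c] for c in chrom_lengths
    }
    total_weight = sum(
        chrom_lengths[c] + (b - 1.0) * sum(e - s for s, e in plant_runs[c])
        for c in chrom_lengths
    )

    def window_weight(chrom: str, lo: int, hi: int) -> float:
        lo, hi = max(0, lo), min(chrom_lengths[chrom], hi)
        if hi <= lo:
            return 0.0
        inside = sum(
            max(0, min(hi, e) - max(lo, s)) for s, e in plant_runs[chrom]
        )
        return (hi - lo) + (b - 1.0) * inside

    w_lo, w_hi = spec.width_range
    probs = [
        window_weight(interval.chrom, interval.start - w + 1, interval.end)
        / total_weight
        for w in range(w_lo, w_hi + 1)
    ]
    return float(np.mean(probs))


def _simulate_editing(rng, ann: AnnotationSet, density: float):
    exons = ann.exons()
    total = sum(e.length for e in exons)
    if total == 0 or density <= 0:
        return []
    n_sites = rng.binomial(total, min(1.0, density))
    offsets = np.sort(rng.choice(total, size=n_sites, replace=False))
    sites = []
    bounds = np.cumsum([0] + [e.length for e in exons])
    for k, off in enumerate(offsets):
        i = int(np.searchsorted(bounds, off, side="right") - 1)
        pos = exons[i].start + int(off - bounds[i])
        sites.append(GenomicInterval(exons[i].chrom, pos, pos + 1, f"edit_{k + 1}"))
    return sorted(sites)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CodonAlnSpec:
    n_codons: int
    n_species: int
    substitution_rate: float = 0.3  # per third-position site per species
    constraint_mode: str = "free"  # free | synonymous_only | invariant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("need >= 1 codon")
        if self.constraint_mode not in ("free", "synonymous_only", "invariant"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")


@dataclass
class CodonAlignment:
    species: list[str]
    sequences: dict[str, str]
    reference: str  # species label of the reference row


@dataclass
class CodonTruth:
    """Per third-position site: did any species acquire a synonymous /
    nonsynonymous substitution relative to the reference?"""

    synonymous: list[bool]
    nonsynonymous: list[bool]


def simulate_codon_alignment(spec: CodonAlnSpec) -> tuple[CodonAlignment, CodonTruth]:
    from .codon import translate_codon  # local import to avoid a cycle

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    bases = "ACGT"

    ref_codons = []
    while len(ref_codons) < spec.n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            ref_codons.append(c)

    species = [f"sp{i}" for i in range(spec.n_species)]
    seqs = {species[0]: "".join(ref_codons)}
    truth_syn = [False] * spec.n_codons
    truth_non = [False] * spec.n_codons

    for sp in species[1:]:
        codons = []
        for i, ref in enumerate(ref_codons):
            codon = ref
            if (
                spec.constraint_mode != "invariant"
                and rng.random() < spec.substitution_rate
            ):
                ref_aa = translate_codon(ref)
                alts = [b for b in bases if b != ref[2]]
                if spec.constraint_mode == "synonymous_only":
                    alts = [
                        b for b in alts if translate_codon(ref[:2] + b) == ref_aa
                    ]
                if alts:
                    alt = alts[int(rng.integers(0, len(alts)))]
                    cand = ref[:2] + alt
                    if cand in _STOPS:
                        cand = codon  # never introduce an in-frame stop
                    if cand != codon:
                        codon = cand
                        if translate_codon(codon) == ref_aa:
                            truth_syn[i] = True
                        else:
                            truth_non[i] = True
            codons.append(codon)
        seqs[sp] = "".join(codons)

    aln = CodonAlignment(species, seqs, species[0])
    return aln, CodonTruth(truth_syn, truth_non)
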