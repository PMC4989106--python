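"""End-to-end orchestration: run the detection and downstream analyses from
a structured YAML config with reproducible seeds and a run manifest.

Stage order mirrors the analysis: simulate (optional) -> detect ->
classify -> reference -> cluster -> distances -> enrich -> multifun.
Every random choice flows from the single config seed via named
substreams; re-running an identical config reproduces all deterministic
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import context, enrichment, io, simulate
from .detect import DetectionConfig, detect_uces
from .model import GenomeCohort, GenomicInterval

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "detect", "classify", "reference", "cluster",
    "distances", "enrich", "multifun",
)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs (either simulate or load from disk)
    simulate_cohort: dict | None = None
    simulate_tracks: dict | None = None
    reference_fasta: str | None = None
    query_fastas: list[str] = field(default_factory=list)
    gff3: str | None = None
    peak_beds: dict[str, str] = field(default_factory=dict)  # factor -> path
    editing_bed: str | None = None
    # parameters
    k: int = 50
    min_length: int = 50
    strand_mode: str = "both"
    cluster_threshold: str | int = "median"  # "median" or a fixed gap in nt
    null_replicates: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _preflight(cfg: RunConfig) -> None:
    wants_cohort = {"detect", "classify", "reference", "cluster", "distances",
                    "enrich", "multifun"} & set(cfg.stages)
    if wants_cohort and cfg.simulate_cohort is None:
        for path in [cfg.reference_fasta, *cfg.query_fastas]:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input missing: {path}")
    needs_ann = {"classify", "multifun"} & set(cfg.stages)
    if needs_ann and cfg.simulate_tracks is None and cfg.gff3 is None:
        raise FileNotFoundError("annotation (gff3 or simulate_tracks) required")
    if "enrich" in cfg.stages and cfg.simulate_tracks is None and not cfg.peak_beds:
        raise FileNotFoundError("peak tracks required for the enrich stage")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the run
    manifest (also written to <out_dir>/manifest.json)."""
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    counts: dict[str, int] = {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_sim, seed_tracks, seed_ref, seed_null = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )

    # --- inputs -----------------------------------------------------------
    truth = None
    tracks = None
    if cfg.simulate_cohort is not None:
        spec = _cohort_spec(cfg.simulate_cohort, seed_sim)
        cohort, truth = simulate.simulate_cohort(spec)
        io.write_fasta(out / "reference.fa", cohort.reference)
        for name, g in zip(cohort.query_names, cohort.queries):
            io.write_fasta(out / f"{name}.fa", g)
        io.write_bed(out / "truth_plants.bed", truth.plants)
    else:
        cohort = GenomeCohort(
            io.read_fasta(cfg.reference_fasta),
            [io.read_fasta(q) for q in cfg.query_fastas],
        )
    if cfg.simulate_tracks is not None and truth is not None:
        tspec = _track_spec(cfg.simulate_tracks, seed_tracks)
        tracks = simulate.simulate_tracks(cohort, tspec, truth)
        io.write_gff3(out / "annotations.gff3", tracks.annotations)
    elif cfg.gff3 is not None:
        ann = io.read_gff3(cfg.gff3)
        from .model import PeakSet

        peak_sets = [
            PeakSet(factor, "all", io.read_bed(path))
            for factor, path in cfg.peak_beds.items()
        ]
        editing = io.read_bed(cfg.editing_bed) if cfg.editing_bed else []
        tracks = simulate.Tracks(ann, peak_sets, editing)

    # --- detect -----------------------------------------------------------
    uces = []
    if "detect" in cfg.stages:
        dcfg = DetectionConfig(cfg.k, cfg.min_length, cfg.strand_mode)
        uces, dmanifest = detect_uces(cohort, dcfg)
        io.write_bed(out / "uces.bed", uces)
        io.write_fasta(out / "uces.fa", {u.name: u.sequence for u in uces})
        counts["detect"] = len(uces)
    else:
        dmanifest = {}

    # --- classify ---------------------------------------------------------
    by_class: dict[str, list[GenomicInterval]] = {}
    if "classify" in cfg.stages and tracks is not None:
        by_class = context.classify_all(uces, tracks.annotations)
        rows = []
        for cls, members in by_class.items():
            for m in members:
                rows.append(GenomicInterval(m.chrom, m.start, m.end,
                                            f"{m.name}|{cls}"))
        io.write_bed(out / "uce_classes.bed", sorted(rows))
        counts["classify"] = len(rows)

    # --- reference elements ----------------------------------------------
    ref_elements: list[GenomicInterval] = []
    if "reference" in cfg.stages:
        lengths = [u.length for u in uces] or [cfg.min_length]
        ref_elements = context.generate_reference_elements(
            cohort.reference, lengths, seed_ref
        )
        io.write_bed(out / "reference_elements.bed", ref_elements)
        counts["reference"] = len(ref_elements)

    # --- cluster ----------------------------------------------------------
    dist = {}
    if "distances" in cfg.stages and ref_elements:
        dist = context.distance_stats(
            uces, ref_elements, n_null=cfg.null_replicates, seed=seed_null
        )
        (out / "distance_stats.json").write_text(json.dumps(dist, indent=1))
    if "cluster" in cfg.stages:
        if cfg.cluster_threshold == "median":
            threshold = dist.get("observed_median")
            if threshold is None:
                gaps = context._gaps(uces)
                threshold = float(np.median(gaps)) if gaps.size else 0.0
        else:
            threshold = float(cfg.cluster_threshold)
        clusters = context.cluster_elements(uces, threshold)
        io.write_bed(
            out / "clusters.bed",
            [
                GenomicInterval(c.chrom, c.start, c.end,
                                f"cluster_{i + 1}|n={c.n_members}")
                for i, c in enumerate(clusters)
            ],
        )
        counts["cluster"] = len(clusters)
        counts["clustered_elements"] = sum(c.n_members for c in clusters)

    # --- enrichment -------------------------------------------------------
    if "enrich" in cfg.stages and tracks is not None and ref_elements:
        ref_by_class = context.classify_all(ref_elements, tracks.annotations)
        scan_elements = {
            c: v for c, v in by_class.items() if c in enrichment.SCAN_CLASSES
        }
        results = enrichment.factor_scan(
            scan_elements, ref_by_class, tracks.peak_sets
        )
        enrichment.results_frame(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        counts["enrich"] = len(results)

    if "multifun" in cfg.stages and tracks is not None and ref_elements:
        coding = tracks.annotations.exons()
        sites = tracks.annotations.splice_sites()
        prof_el = enrichment.function_profiles(
            uces, coding, sites, tracks.editing_sites, tracks.peak_sets
        )
        prof_ref = enrichment.function_profiles(
            ref_elements, coding, sites, tracks.editing_sites, tracks.peak_sets
        )
        mf = enrichment.multifunctionality(prof_el, prof_ref)
        (out / "multifunctionality.json").write_text(json.dumps(mf, indent=1))
        enrichment.combo_fold(prof_el, prof_ref).to_csv(
            out / "combo_folds.tsv", sep="\t", index=False
        )
        counts["multifun"] = len(prof_el)

    manifest = {
        "tool": "ucekit 0.1.0",
        "config": {k: v for k, v in vars(cfg).items()},
        "detection": dmanifest,
        "row_counts": counts,
        "seed": cfg.seed,
        "elapsed_s": round(time.time() - t0, 3),
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, default=str))
    tmp.rename(out / "manifest.json")
    return manifest


def _cohort_spec(raw: dict, seed: int) -> simulate.CohortSpec:
    plants = [simulate.PlantSpec(**p) for p in raw.get("planted_elements", [])]
    decoys = [simulate.DecoySpec(**d) for d in raw.get("decoy_elements", [])]
    return simulate.CohortSpec(
        n_species=raw.get("n_species", 4),
        chrom_lengths=raw.get("chrom_lengths", [5000]),
        background_divergence=raw.get("background_divergence", 0.2),
        planted_elements=plants,
        decoy_elements=decoys,
        seed=raw.get("seed", seed),
    )


def _track_spec(raw: dict, seed: int) -> simulate.TrackSpec:
    peak_tracks = [
        simulate.PeakTrackSpec(**p) for p in raw.get("peak_tracks", [])
    ]
    kwargs = {k: v for k, v in raw.items() if k != "peak_tracks"}
    kwargs.setdefault("seed", seed)
    return simulate.TrackSpec(peak_tracks=peak_tracks, **kwargs)
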