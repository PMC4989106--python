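# ucekit

Alignment-free discovery of **ultraconserved elements (UCEs)** — genomic
segments of at least 50 nt whose sequence is exactly identical across every
genome in a cohort — together with the downstream analyses used to
characterize them as gene-regulatory hubs: genomic classification against
gene models, a length-matched uniquely-mapping null model, element
clustering and distance statistics, transcription-factor / Polycomb
enrichment scans, per-element multifunctionality scoring, and a
synonymous-site test showing when coding constraint alone cannot explain an
ultraconserved exon.

The package is aimed at comparative and regulatory genomicists working with
cohorts of related assemblies (the motivating system is *Drosophila*:
*D. melanogaster* plus 11 congeneric species), and at method developers who
need a fully synthetic, ground-truthed test bed for conservation pipelines.

## The method

**Detection.** Instead of a whole-genome alignment, ucekit uses a
seed-and-verify scheme:

1. extract every k-mer (k = 50 by default) that occurs **exactly once** in
   the reference genome, counting occurrences on both strands (a k-mer and
   its reverse complement are the same word; palindromic k-mers count
   themselves twice and are never unique);
2. keep seeds whose k-mer has a **perfect match in every query genome**
   (either strand);
3. **fuse** genomically overlapping seeds — windows at positions *p* < *q*
   overlap iff *q* − *p* ≤ *k* − 1 — into maximal candidate intervals;
4. **verify** that each candidate's full reference sequence occurs in every
   query genome; a failing (chimeric) candidate is recursively bisected at
   its median seed and the verified sub-elements ≥ 50 nt are emitted.

Uniqueness makes each seed an unambiguous genomic address; universality
makes it ultraconserved; verification guards against candidates stitched
together from seeds that match different loci in a query.

**Null model.** All enrichment statistics compare elements against
*reference elements*: the genome tiled left-to-right into fragments drawn
from the observed UCE length distribution, discarding fragments containing
N or mapping to more than one site (both strands). Enrichment per factor ×
element class is a 2×2 χ² test (Yates-corrected) with Benjamini–Hochberg
correction across the whole family; multifunctionality assigns each element
a 0–4 score (protein-coding overlap, splice-site overlap, RNA-editing site,
TF-peak overlap) compared by Mann–Whitney, with per-combination folds over
the 2⁴ flag patterns.

**Coding-constraint test.** For an ultraconserved exon, the synonymous-site
census asks, per codon third position relative to a reference row, whether
the site *could* change synonymously (every sense codon except ATG/Met and
TGG/Trp) and whether any species *did*. A 2×2 Fisher exact test
(two-sided, minimum-likelihood rule) against a baseline alignment under the
same substitution regime tests whether the exon's lack of synonymous change
is explicable by chance.

## Worked example

```python
from ucekit import (CohortSpec, PlantSpec, DecoySpec, simulate_cohort,
                    detect_uces, fisher_exact_2x2)

# a 5-species cohort: reference + 4 queries diverged 20% per site,
# two planted identical elements, one near-identical decoy
spec = CohortSpec(
    n_species=5, chrom_lengths=[5000], background_divergence=0.2,
    planted_elements=[PlantSpec(60, 0, 800), PlantSpec(110, 0, 2400)],
    decoy_elements=[DecoySpec(80, 0, 4000, n_mismatches=1)],
    seed=42,
)
cohort, truth = simulate_cohort(spec)
uces, manifest = detect_uces(cohort)
for u in uces:
    print(u.name, u.chrom, u.start, u.end, u.length)

p = fisher_exact_2x2([[0, 15], [29, 28]])
print(f"P = {p:.4f}")
```

prints

```
uce_1 chr1 800 860 60
uce_2 chr1 2400 2512 112
P = 0.0002
```

Both planted elements are recovered (the second extended by two flanking
bases that happen to be identical in all five genomes — exactly what the
definition demands), and the single-mismatch decoy at 4000–4080 is
rejected. The Fisher p compares an exon with 0 of 15 synonymous-capable
sites substituted against a baseline with 29 of 57: the lack of synonymous
change is not explicable by chance (P = 0.0002).

The same stages are available from the shell:

```sh
ucekit detect --reference ref.fa --query q1.fa --query q2.fa --out out/
ucekit cluster --elements out/uces.bed --threshold 18000 --out clusters.bed
ucekit codonstats --exon mI.fa --baseline homeodomain.fa --reference-species dmel
ucekit run --config pipeline.yaml   # simulate -> detect -> ... -> multifun
```

## Layout

```
src/ucekit/
  simulate.py    synthetic cohorts, annotation/peak/editing tracks,
                 codon alignments — all with ground truth
  detect.py      seed-and-verify UCE detection
  context.py     classification, reference elements, clustering, distances,
                 gene ranking
  enrichment.py  chi-square/BH/Mann-Whitney kernels, factor scan,
                 multifunctionality, alt-splicing and ESE motif tests
  codon.py       synonymous-site census and Fisher exact test
  pipeline.py    YAML-configured end-to-end runs with manifests
  cli.py         `ucekit` command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
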