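# Methods

## Definitions and coordinate conventions

A UCE is a reference-genome interval of at least `min_length` nt (default
50) whose sequence occurs exactly — on either strand by default — in every
query genome of the cohort. All coordinates are 0-based half-open (BED
convention) on the reference assembly; BED6, GFF3 (converted at the I/O
boundary) and 60-column-wrapped FASTA are the on-disk formats. Soft-masked
(lowercase) bases are uppercased before indexing because exact sequence
identity is case-insensitive biologically; windows containing N are never
seeds and never reference elements.

## Detection

Seeds are reference k-mers (k = 50) occurring exactly once genome-wide.
Uniqueness counts forward occurrences plus occurrences of the reverse
complement anywhere, so a palindromic k-mer counts itself twice and is
excluded; this mirrors how a short-read mapper run in both-strand mode
would count. `strand_mode="forward"` restricts both the uniqueness count
and the query match to the forward strand and exists mainly so tests can
use a simpler oracle.

Universal seeds (perfect match in every query, either strand) are fused
when their windows genomically overlap: positions *p* < *q* fuse iff
*q* − *p* ≤ *k* − 1. Fusion is transitive and the fused runs are maximal.
Each candidate's full sequence is then re-checked against every query
genome. Multiple matches within one query are allowed: uniqueness is a
reference-side constraint only (the null model additionally demands unique
mapping, below).

A candidate can fail verification when its seeds match different loci in
some query (a chimera). Failed candidates are bisected at the median seed
index; each half is re-fused and re-verified recursively, and verified
sub-elements of at least `min_length` are emitted. The two halves of one
failed candidate share the boundary region, so verified halves can overlap
on the reference; the final pass trims the later element at the earlier
element's end — a substring of a universal sequence is itself universal, so
the trimmed element remains valid — and drops it if it falls below
`min_length`. Unverifiable remainders are logged, never raised.

Detection holds all reference k-mers in memory (a Python dict) and one
k-mer set per query genome; this is comfortable for cohort sizes up to tens
of megabases per genome on a single CPU. For full fruit-fly-scale cohorts
the same contract can be served by a disk-backed k-mer index; the module
boundary (`extract_unique_kmers` / `is_universal`) is where such a backend
would plug in.

## Synthetic cohorts (what the generator emulates, and what it does not)

`simulate_cohort` produces one reference genome (i.i.d. uniform ACGT) and
N query genomes, each equal to the reference with i.i.d. substitutions at
`background_divergence` per site — a star phylogeny. This is deliberate:
the detector is tree-agnostic (it only asks "identical everywhere or
not"), so shared internal branches would change nothing about the
contract being tested while complicating the ground truth. Planted
elements receive zero substitutions in every species and are the true
UCEs; they must be pairwise separated by ≥ 50 nt so that two plants can
never merge into one detected element. Decoys emulate the near-identical
false-positive mode seen in real assemblies (duplicated or mis-assembled
copies differing by a single mismatch): a decoy region is
substitution-free except for exactly `n_mismatches` planted mismatches per
target species, spread evenly so no identical run inside the decoy reaches
50 nt. Default study conditions used in tests and the acceptance sweep:
3 kb chromosomes, 3–6 species, divergence 0–0.3, plants of 50/75/120 nt,
one 80-nt single-mismatch decoy — divergence 0.2 being the regime where
a 50-mer surviving by chance in all queries is vanishingly rare while
single-base chance extensions of a planted element at its flanks are
common enough to exercise the maximality semantics.

Not emulated: indels, rate heterogeneity, GC bias, repeat families,
assembly gaps beyond optional N-runs, and codon models beyond the three
constraint modes below. Passing tests therefore demonstrate correctness of
the algorithmic contracts, not robustness to alignment artifacts (which
the alignment-free design sidesteps by construction) or to assembly error
beyond the decoy mode.

`simulate_tracks` draws gene models (exon/intron sizes Poisson around
configurable means), ncRNAs, editing sites (binomial over exonic bases)
and per-factor peak tracks. Peak start positions follow a
piecewise-constant density with weight `uce_bias` inside planted elements
and 1 elsewhere, so bias 1 is exactly placement independent of the
elements. `expected_overlap_probability` integrates this density in closed
form; the bias-calibration tests compare 10⁴ Monte-Carlo placements to it
within 3 binomial standard errors.

`simulate_codon_alignment` mutates third codon positions at a per-site,
per-species rate under three regimes — `free`, `synonymous_only` (the
substitution is resampled among amino-acid-preserving alternatives),
`invariant` — recording per-site truth flags at generation time. In-frame
stops are never introduced.

All generators derive independent substreams from a single integer seed
(`numpy.random.SeedSequence.spawn`), so identical specs give byte-identical
FASTA/BED/GFF3 output.

## Genomic context

Classification priority is ncRNA → junction → exonic → intronic →
intergenic, where "junction" means the element overlaps ≥ 1 exonic base
*and* ≥ 1 intronic base of the same transcript, and one qualifying
transcript suffices. Testing junction before plain exon overlap keeps
boundary-spanning elements out of the "exonic" count, which matches
treating junctions as their own category; the classification is total, so
the five class counts always sum to the element count.

Reference elements tile each chromosome left-to-right with lengths drawn
(seeded, with replacement) from the observed element-length multiset;
fragments containing N or mapping non-uniquely (both strands) are
discarded, which preserves the length distribution because discarding is
independent of the drawn length in non-repetitive sequence.

Clustering is single-linkage chaining of sorted same-chromosome elements
with inter-element gap (next start − previous end) strictly below the
threshold; a cluster needs ≥ 2 members, so singletons stay unclustered.
The default pipeline threshold is the observed median gap (the published
*Drosophila* analysis used its observed median, 18 kb); a fixed threshold
can be configured.

`distance_stats` compares observed gaps to a null built by drawing
|elements| members from the reference-element set per replicate (100
replicates by default) — the reference set already encodes length matching
and unique mappability, and drawing the observed element *count* keeps the
null's density comparable. The expected median is the mean of
per-replicate medians; the test is a two-sided Mann–Whitney of observed
gaps against the pooled null gaps. Because the gaps of one realization sum
to (almost) the covered span, they are negatively correlated and the test
is *conservative*: its p-values are stochastically larger than uniform
under the null (we measured the deficit directly), so significance calls
are trustworthy but the p-value should not be read as an exact tail
probability. The gene ranking divides the element count in each gene span
± 10 kb by the reference-element count in the same window, excluding (and
logging) genes with an empty denominator.

## Enrichment statistics

χ² on 2×2 tables uses the Yates continuity correction by default — for
2×2 tables the adjusted-expected form is algebraically the textbook
n(|ad−bc|−n/2)²/(r₁r₂c₁c₂), which the tests pin to the hand value
11.28125 — and a zero row or column margin yields an "untestable" result
rather than an exception. Benjamini–Hochberg adjustment is applied once
per analysis family (all factor × class tests jointly; all ESE motifs
jointly), never pooled across analyses; untestable rows are excluded from
the family size. Mann–Whitney is exact for groups of ≤ 8 (full
permutation enumeration when ties are present, since the U null is
symmetric this equals the |U − E[U]| tail sum) and a tie-corrected normal
approximation otherwise.

The factor scan tests the classes intergenic / intronic / exonic;
ncRNA-overlapping elements are excluded upstream because highly expressed
ncRNAs are a known source of spurious ChIP signal. Datasets for one
Polycomb/Trithorax protein should be merged by interval union before
testing (the `PeakSet` for such a protein is simply the merged set). The
χ² independence assumption requires that overlap indicators of different
elements be effectively independent: elements packed more densely than the
peak width share peaks, and the familywise false-positive rate inflates
accordingly (we observed 27% nominal-5% calls at 4× overpacking). The
calibration fixtures therefore keep mean element spacing several times the
peak width, which is also the regime of real UCE data (median inter-element
distances in the tens of kilobases versus peak widths in the hundreds of
bases).

Multifunctionality flags are ≥ 1-base overlaps: coding (any annotated
exon), splice site (an exon terminal base adjacent to an intron — a 1-nt
point definition), editing (site positions), TF binding (union of all
factors' peaks: "bound by at least one factor"). The combination table
enumerates all 2⁴ flag patterns with per-cohort proportions and their
ratio; a pattern with zero reference proportion but nonzero element
proportion reports an infinite fold with the raw counts alongside.

## Codon-level constraint

The census is strictly third-position and strictly pairwise against the
designated reference row (no ancestral reconstruction): a site is
synonymous-capable iff some alternative third-position base preserves the
amino acid (exhaustively: all sense codons except ATG and TGG), and
substituted-synonymous iff ≥ 1 species differs at the third position with
the amino acid preserved — the "at least one species" reading; differences
at first/second positions are ignored. Columns containing gaps or ambiguity
codes are excluded with logging; an in-frame stop in the reference is an
error naming the codon.

Fisher's exact test is two-sided by the minimum-likelihood rule: the p
is the sum of hypergeometric probabilities (log-space) of all tables with
the observed margins whose probability is ≤ the observed table's
probability × (1 + 10⁻⁷). The tolerance absorbs floating-point ties; the
two-sided rule (not double-one-sided) is what reproduces the published
P = 0.0002 for the 0/15-vs-29/28 comparison (a one-sided test gives
≈ 0.0001). Like all discrete exact tests it is conservative: null
p-values are super-uniform, and the calibration test asserts validity
(P(p < 0.05) ≤ 0.05), not uniformity. dN/dS estimation is out of scope
(it requires a codon-model ML fit over a phylogeny; the census
deliberately avoids any tree).

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen so every stochastic check has
clear resolution at 3 standard errors while the whole suite stays
desk-scale: 200 seeded cohorts (3 kb, 3–6 species) for the
detector-vs-oracle sweep; 100 simulated families for factor-scan
calibration and power; 10⁴ placements for peak-bias calibration; 200
replicates for the test-validity checks. Ties in gene ranking are broken
by gene id; cluster thresholds compare with strict inequality (a gap equal
to the threshold does not join); manifests are written atomically
(temp-file rename) and record parameters, seeds, row counts and genome
checksums sufficient to re-run deterministic stages bit-identically.

## Known limitations

- Memory-resident k-mer indexing bounds practical cohort size (tens of Mb
  per genome); a disk-backed index is a drop-in extension, not included.
- The star-phylogeny generator cannot probe tree-shaped correlation in
  substitution placement (irrelevant to the detection contract, relevant
  if one wanted realistic counts of chance-conserved elements).
- The distance-statistic and Fisher p-values are conservative, as
  described above.
- Synteny is not checked: an element present in every genome but at a
  non-orthologous locus in some species is still reported (the decoy
  machinery exists precisely to quantify this failure mode in synthetic
  data).
- The ESE motif scan is exact substring matching on the sense strand; no
  PWM scoring.
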