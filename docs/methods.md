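# Methods

## Scope and design

`magmirror` implements the desk-scale core of an ecosystem-mirroring
benchmark framework for MAG pipelines: reference-database construction,
mirror-specification building, read simulation, ground-truth mapping,
base-pair evaluation, contig-level bias analysis, simulation-fidelity
metrics, and a synthetic-data generator that plants every structure the
analyses study. External bioinformatics tools are deliberately out of
process: the package parses their tabular dialects (Sylph profile/query,
BLAST outfmt 6, CheckM2, GUNC, geNomad provirus tables, bin membership
TSVs) and emits exact command lines (InSilicoSeq) where a full-scale run
would invoke them. Every operation is therefore testable end-to-end with
no downloads and no subprocesses.

## Reference database

Genomes arrive preclustered at the species level (95% ANI) with one
designated representative per cluster; this metadata is trusted as given.
Strain clusters (98% ANI) are assigned within each species cluster by
greedy seed agglomeration: genomes visited in descending total length
(ties lexicographic by id) either join the first existing cluster whose
*seed* is ≥ 98% ANI with them or seed a new cluster. This is a
deterministic O(n²) stand-in for dRep's secondary clustering; when real
dRep output is available its pairwise-ANI table is used verbatim through
the `ani_table` adapter, which is the authoritative path for full-scale
replication.

The built-in ANI estimator uses canonical k-mer (k = 21) containment
c = |K_a ∩ K_b| / min(|K_a|, |K_b|) mapped through
ANI = 100·(1 + ln(2c/(1+c))/k), clamped to [0, 100], with c = 0 → 0. This
closed form inverts the expected k-mer survival under i.i.d.
substitutions; it is biased upward at larger divergences (≈ 98.3 at 3%
true divergence), which is acceptable for its two uses — separating
same-strain (≥ 98%) from different-species (≤ 85%) pairs, and ranking —
but it is not an alignment-based ANI. N50 uses the standard convention:
with lengths sorted descending, the length at which the cumulative sum
first reaches half the total.

## Built-in profiler

A k-mer containment stand-in, not a replica of any profiler's statistical
model. Species abundance: each read is assigned to the species
representative with maximal containment of the read's canonical k-mers
(ties to the smaller species id); abundances are assigned-read fractions.
Per-genome rows: adjusted ANI from the containment of the genome's k-mers
in the pooled read k-mer set, through the same closed form; the CI lower
bound from a normal approximation on the containment (±1.96 SE). The
effective-coverage token is "LOW" below a matched-read floor (default 50
reads), "HIGH" at ≥ 10× the floor, and the numeric coverage estimate in
between — matching the three-way branch the downstream gate takes.
Column names of the external profiler dialect are pinned in one
overridable descriptor (`SylphDialect`) because they drift between
versions; the ANI confidence-interval column is parsed as a "lo-hi"
string with the lower bound extracted.

## Mirror specification

Per profiled species, the strain-evidence gate is exactly:
token ≠ "LOW" AND adjusted ANI ≥ 99.8 AND (token = "HIGH" OR CI lower
≥ 99.5), all thresholds inclusive. Gated genomes are grouped by strain
cluster; if more than three clusters qualify, three are drawn uniformly
without replacement. One genome per cluster is chosen by
(isolate, N50, ANI, id) priority; the species abundance is split with
logNormal(μ=1, σ=2) weights — interpreted as exp of a Normal with mean 1
and SD 2 on the natural-log scale, the standard reading of that notation;
the parameterization is isolated in two module constants should the
distribution-mean reading ever be preferred. A species with no gated
genome falls back to a single genome by (isolate, ANI, N50, id) priority,
with genomes absent from the query table ranking below any profiled ANI.

Because profiler abundances need not sum to one (unclassified mass), the
finished specification is renormalized to sum exactly to 1; the read
sampler needs a proper distribution and the specification file *is* the
ground truth, so truth stays exact. One RNG seeded per sample drives both
the random cluster cap and the logNormal draws, and the seed is recorded
in the specification file, making the whole construction reproducible
byte-for-byte.

## Read simulation

The built-in sampler is a provenance-exact substitute for an external
read simulator: per-genome pair counts are multinomial over the
specification abundances (used directly as sequence abundances; a
`length_reweight` switch converts taxonomic to sequence abundance since
profiler semantics are ambiguous), fragments start uniformly on a
length-weighted random sequence, strands are random, mate 2 is the
reverse complement of the fragment end, substitution errors are i.i.d.
(default 0), and qualities are constant Phred 30. `num_reads` is
interpreted as total read *pairs* by default (`num_pairs` overrides).
Read length defaults to 126 bp and the insert to 300 ± 25 bp, typical
values for the HiSeq-class short-read data this mirrors. Error models,
indels and duplicates belong to the external path, for which the exact
InSilicoSeq command (`--model HiSeq`, `--n_reads`, draft and abundance
files) is emitted instead.

Expected coverage of genome g is
abundance_g · num_reads · read_length · 2 / length_g (paired), the
quantity consumed by the ≥ 2.5× coverage filter.

## Ground truth and evaluation

BLAST tabular (outfmt 6) hits are converted at the parser boundary to
0-based half-open coordinates with subject intervals
orientation-normalized; internally everything is interval arithmetic.
Qualifying hits require identity ≥ 99% and alignment length within
99–101% of the contig length (both ends inclusive). Multiple qualifying
hits of one contig to one genome are all retained and later unioned —
counting covered genome basepairs correctly for split/repeat hits; a
best-hit-only mode was rejected because it undercounts exactly the
repeat-rich regions the bias analysis cares about. The built-in
`oracle_align` finds exact substring occurrences on both strands, which
suffices for fixtures whose contigs are planted verbatim.

TP per (genome, bin) is the per-sequence interval-union of genome bases
covered by the bin's qualifying contigs; FN is the complement to genome
length. The representative bin maximizes recall, ties broken by
lexicographically smallest bin id (the choice is arbitrary but must be
deterministic); several genomes may share one representative. FP counts
contig-side bases of the representative bin not covered by qualifying
intervals to the genome — partial, not all-or-nothing per contig, reading
"bases that do not map" literally; under the 99–101% length gate the two
readings differ by ≤ 1% per mapped contig. A contig mapping to several
genomes contributes TP to each and FP to none of them, which is what
makes shared-contig recall meaningful. precision is defined 0 when
TP = FP = 0. The evaluator is verified exactly against a brute-force
per-base boolean-array oracle on randomized instances.

Assembly recall divides the representative bin's TP by the union of
genome bases covered by *any* qualifying contig, and is reported missing
when nothing of the genome assembled. MIMAG-style classes: HQ iff
completeness > 90 and contamination < 5; MQ iff completeness ≥ 50 and
contamination < 10; LQ iff contamination < 10; else UNCLASSIFIED
(contamination estimates may exceed 100).

## Contig-level analyses

Composition distance: cosine distance between 136-dimensional canonical
tetranucleotide frequency vectors (4-mers pooled with reverse
complements; windows with non-ACGT skipped). Coverage distance: Euclidean
distance between a contig's cross-sample coverage vector and the
unweighted mean vector of its genome's contigs; coverage defaults to
truth-derived fragment counts from read provenance (exact at desk scale),
with a TSV adapter for external depth tables.

Percentile discretization pools (contig, genome) items across samples,
orders by distance (ties by sample, contig, genome ids — determinism the
ordering rule must supply), and assigns item c with cumulative preceding
length s_c and length l_c to percentile p satisfying
p·bases < s_c + l_c/2 ≤ (p+1)·bases, bases = total length / 100. The
assignment is computed in exact integer arithmetic (scale by 200), so the
midpoint inequality holds verbatim item-by-item. One pooling is computed
per assembler and reused across binners compared on the same axes.

A contig is prophage if, in any genome it maps to, its interval is inside
a provirus, contains one, or covers ≥ 25% of one (provirus intervals from
a geNomad-style table filtered at virus score ≥ 0.9, or planted fixture
truth). A contig is shared if it has qualifying hits to ≥ 2 recoverable
genomes. Group recall (all / prophage / shared) is correct-bp over
total-bp within the genome's contigs of the group, missing for empty
groups.

## Fidelity and context selection

Shannon α = −Σ p ln p over nonzero taxa (renormalized); Bray–Curtis
through scipy; the paired β-diversity regression is OLS of
simulated-pair on original-pair distances (slope, intercept, R²
reported — the zero-intercept variant can be read off the same data, the
free-intercept fit is reported because it exposes additive bias).
MinHash sketches are bottom-s (default s = 1000) sets of seeded
SplitMix64 hashes of canonical 21-mers — stable across runs by
construction; Mash distance uses the merged bottom-sketch Jaccard
estimate and d = −ln(2j/(1+j))/k with sentinel distance 1 at j = 0.
Partial multi-sample context takes the D = 20 nearest non-target samples,
ties by sample id.

## Synthetic data generator

The generator defines the study conditions for every test: per species an
ancestral genome of i.i.d. bases (default 50% GC), strains substituted at
a configured rate (defaults target the interesting regime around the
98% strain boundary: 1% within strains, 5% when distinct strain clusters
are needed, with species unrelated — ANI 0); shared segments copied
verbatim (ANI 100, so shared-contig truth is unambiguous); prophage
insertions with +15% GC over background, which guarantees
composition-distance separation so the bias machinery is exercisable;
fragmentation into geometric-length contigs (mean 2 kb, floor 500 bp)
tiling each genome exactly, with seeded withholding of contigs for
coverage loss; oracle bins by source genome and corrupted bins with
controlled swap/drop fractions; and CheckM2/GUNC-dialect quality tables
derived from true recall/precision plus configurable noise and bias.
Everything is seed-deterministic and byte-identical across runs.

What the fixtures do not emulate: realistic sequencing error models,
chimeric assembler artifacts, real phage biology, inter-sample strain
drift. Passing tests therefore demonstrate the *accounting* is exact and
the pipeline logic correct under controlled conditions, not that any
specific binner will perform comparably on real data.

Problem sizes used by the test suite and the acceptance script — genomes
of 10–100 kb, collections of 3–7 genomes, 1.5–100 k read pairs, 20–50
seeds per property — were chosen so each property is tested at
statistical power appropriate to its tolerance while the whole suite
stays fast enough to run habitually.

## Known limitations

- The built-in ANI estimator saturates near 100% and is upward-biased at
  larger divergence; real replication should feed dRep/fastANI tables
  through the adapter path.
- The built-in profiler's CI is a normal approximation on containment; it
  branches correctly around the gate but its coverage probability is not
  calibrated.
- Multi-sample binning modes are supported at the data-model level
  (context selection, sample-prefixed contig names); co-abundance feature
  generation for binners is external by design.
- Statistical modeling of evaluation results (mixed models, marginal
  means) is out of scope: the tidy per-genome table is the export surface
  for external statistics packages.
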