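# Methods

This note records the model, the parameter choices, the numerical
conventions and the limits of what the test suite demonstrates.

## Windowed minhash model

References are cut into windows of `window_len` bp overlapping by
`k − 1` bp (stride `window_len − k + 1`), so each k-mer of a genome lies
in exactly one window apart from the duplicated overlap. Truncated final
windows are kept while they contain at least one k-mer (length ≥ k);
dropping them would leave trailing k-mers unindexed. Coordinates are
0-based, half-open everywhere.

K-mers are encoded 2 bits per base (A=0, C=1, G=2, T=3, most-significant
base first) and canonicalized to the numeric minimum of the forward and
reverse-complement codes. The encoding and tie rule are conventions of
this implementation, chosen for platform-independent reproducibility.
Lower-case (soft-masked) bases are treated as their upper-case base;
k-mers containing any other character are skipped deterministically.

Hashing uses a splitmix64-style finalizer with fixed constants. It is a
bijection on 64 bits, so distinct canonical k-mers never collide, and it
has no seed: a database built today is valid forever. A window's sketch
is the `sketch_size` smallest *distinct* hash values (set semantics, as
required for the Jaccard estimator). The bottom-s estimator
`estimate_similarity` returns, among the s smallest values of the union
of two sketches, the fraction present in both; its standard error is
≈ √(J(1−J)/s), which bounds what any test of it can assert.

## Database semantics

Keys map to location lists sorted by (target id, window id); building is
therefore insertion-order independent. Lists longer than `max_locations`
(default 254) mark the key uninformative: the key is removed entirely at
finalization, and the database remembers removed keys so that later
`add_references` calls cannot resurrect them (the alternative —
recounting from scratch on every extension — would make extension as
expensive as rebuilding; the consequence is that an extended database
can differ from a fresh union build only in keys that had already
overflowed). Conservation holds exactly: stored locations plus locations
lost to overflow equal the total staged insertions.

Partitioning assigns whole genomes (never splitting one) to `n` buckets
greedily, longest genome first into the currently lightest bucket, ties
broken by ascending target id and ascending bucket index. The spread
between bucket loads is bounded by the largest single genome. Target
ids are global across partitions, so per-partition results merge without
translation. Partition files are single little-endian binaries (magic,
version, JSON header with parameters and target table, packed key and
location arrays, CRC32); a JSON manifest lists the partition files and
embeds the taxonomy, so querying needs only the database directory.

## Classification

The per-query window count statistic accumulates one count per returned
location per sketch value; both mates of a pair share it. The scored
range width is `ceil(max_fragment / stride) + 1` windows, with
`max_fragment` defaulting to 3× read length for pairs and the read
length for singles — wide enough for a 101 bp single read spanning a
window border (2 windows at defaults) or a paired fragment (4 windows).
Per target, a sliding two-pointer pass finds the maximum-sum contiguous
range within that width; earliest range wins ties. Candidates are ranked
by hits descending, then ascending target id (all tie-breaks in the
package are by ascending id, making outputs reproducible), truncated to
`tophits` (default 8) per partition, optionally pruned below `H` hits,
and merged across partitions by the same ordering.

The decision rule needs two thresholds the qualitative description
("significantly higher", "similar count range") leaves open; both are
exposed as knobs with these defaults:

- `min_hits` = ⌈s/2⌉ per sketch queried (4 for singles, 8 for pairs):
  below it a best candidate is considered noise and the read stays
  unclassified. Without a floor, single spurious key matches would
  classify reads.
- `band` = max(2, ⌈0.1 · best⌉): runner-ups within the band are
  near-ties; a single survivor claims the read at its private
  sequence-level taxon, several survivors send it to their LCA. Widening
  the band can only generalize an assignment to an ancestor.

Each reference gets a private "sequence"-rank leaf under its mapped
taxon, so two genomes of one species stay distinguishable per read but
merge at species rank in quantification. With `H = 0` and `tophits` not
limiting, classification over any partitioning equals the unpartitioned
result read for read; `H > 0` trades exactness of the merge for smaller
intermediate candidate sets.

## Coverage filter

Coverage marks the best-range windows of *every* retained candidate of
every read — the filter operates on the candidate list identified during
assignment, before final decisions. Targets are ranked by covered
fraction (ties by id) and the lowest ⌊q·T⌋ are excluded; reads are then
re-assigned from their retained candidate lists with excluded targets
removed, so excluded targets receive exactly zero final reads and
`q = 0` reproduces pass 1 bit for bit. A guard (default: fewer than 5
candidate targets) disables the filter where a fixed quantile of a tiny
candidate set would be meaningless; the approach as such presumes enough
reads to cover genuine genomes substantially.

## Quantification

Counts below the requested rank move up to their at-rank ancestor
("no rank" nodes are transparent and never returned). Counts above the
rank are pushed down level by level, split in proportion to each child
subtree's post-prune read weight; observed reads are the only weight
available without external priors such as genome size. Counts whose
subtree carries no at-rank weight land in an explicit "unassigned" row.
The redistribution runs in exact rational arithmetic, so estimated reads
(including unassigned) sum to the classified total exactly; the
published table holds floats, with percentages relative to classified
reads.

## Synthetic data

The generator emulates calibrator-style mixtures: an ancestor genome
drawn uniformly at random, per-taxon derivation by i.i.d. substitutions
at a stated divergence (close relatives derive from another taxon's
sequence instead), optional unrelated genomes with a planted shared
segment, and reads drawn from a stated composition with i.i.d.
substitution errors, uniform positions and uniform insert sizes.
Substitution-only models (no indels) keep k-mer survival analytically
simple — (1 − e)^k per k-mer — and exercise every code path; they do not
model real-data features such as indels, coverage bias, GC effects,
duplicated or repetitive genome structure, contamination, or empirical
quality profiles. Passing recovery tests therefore demonstrates the
correctness of the machinery under the stated generative model, not
field performance on real samples.

Default study conditions used by the recovery suites:

- *Partition invariance*: four 100 kb genomes at 3–8% divergence from a
  shared ancestor, 10,000 read pairs (101 bp, 1% error), one vs. four
  partitions.
- *Mixture recovery*: an 80/14/5.5/0.5% four-component mixture plus an
  in-database absent relative at 2% divergence from the dominant
  component, 100,000 pairs at 1% error, compared at species rank. The
  two poultry-like minor components use higher ancestor divergences than
  the two mammal-like majors so all between-source distances are large
  against the 2% within-pair distance.
- *Coverage filter*: nine present sources (7–20% each, 20,000 pairs) and
  one absent decoy of unrelated sequence except for a 5 kb segment
  copied from the dominant source. Ten candidates make a 10% quantile
  exclude exactly one target.
- Genome length 100 kb throughout: large enough for ~885 windows per
  genome (stable coverage fractions and window statistics), small enough
  that the full suite runs in minutes on one core.

Evaluation reports `sum_fp`, the summed estimated percentage over taxa
truly absent from the mixture, and `sum_dev`, the summed absolute
deviation from the true composition, with estimates renormalized over
at-rank taxa (excluding the unassigned row) before comparison.

## Numerical and degenerate-input conventions

- Sequences shorter than k yield no windows (logged warning) and empty
  sketches; all-ambiguous queries are unclassified.
- Empty candidate lists, zero classified reads and empty compositions
  produce valid, empty-but-well-formed outputs.
- The Jaccard estimator returns 0 when either sketch is empty.
- Read ids, not positions, key all outputs; per-read output preserves
  input order, abundance rows sort by estimated reads descending.

## Known limitations

- Databases are held fully in memory per partition; partitioning is the
  only memory lever. No memory-mapped serving or compaction.
- No spaced seeds, minimizers, k > 31, or protein alphabets.
- The near-tie `band` and `min_hits` floors are pragmatic defaults, not
  statistically calibrated significance tests.
- Quantification does not correct for genome size or tissue/matrix DNA
  content; a dominant, highly covered genome also dominates LCA
  redistribution weights.
- Taxonomy handling omits merged/deleted taxid remapping.
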