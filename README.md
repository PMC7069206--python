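# sketchtax

Minhash-sketched k-mer window databases for taxonomic classification of
shotgun sequencing reads and quantification of species composition —
aimed at screening applications such as food-ingredient testing and other
mixed-sample metagenomics, where the question is *which organisms are in
this sample, and in what proportions?*

## Method

**Database.** Each reference genome is divided into windows of length
*l* that overlap by *k*−1 bp, so every k-mer belongs to exactly one
window apart from the duplicated overlap. Each window is *sketched*: its
canonical k-mers are hashed with a fixed 64-bit mixing function *h*₁ and
only the *s* smallest hash values are kept, a subsampling by
*S* = (*l*−*k*+1)/*s* (14.125 at the defaults *k*=16, *l*=128, *s*=8).
Every kept value becomes a key in a hash table mapping to a list of
(genome id, window id) locations. Keys accumulating more than a cap
(default 254) of locations are uninformative and deleted at
finalization. Large reference collections are split into disjoint
partitions of whole genomes with roughly equal total length, one
database per partition, bounding peak memory.

**Classification.** A read (or read pair) is sketched the same way and
its sketch values are looked up in each partition. The returned
locations accumulate into a sparse *window count statistic* of hits per
(genome, window). Since a sequenced fragment can straddle window
borders, hits are summed over contiguous window ranges wide enough to
span the fragment; the best range per genome is that genome's candidate.
Per-partition candidate lists merge into a global ranking. The read goes
to the top genome if it clearly outscores the runner-up, to the lowest
common ancestor (LCA) of all near-tied candidates otherwise, and stays
unclassified when the best count is too small.

**Coverage filter.** False positives caused by DNA shared between
reference genomes concentrate their hits in a few windows. After a first
pass, the fraction of read-covered windows is computed per candidate
genome; the lowest quantile (e.g. 10%) of candidates is excluded and
reads are reassigned against the rest.

**Quantification.** Final per-read taxa are converted to abundances at a
requested rank: counts below the rank are pruned up onto their at-rank
ancestor; counts above it are distributed down level by level in
proportion to each child subtree's read weight. Totals are conserved
exactly (exact rational arithmetic internally).

A synthetic-data module (`sketchtax.synthetic`) generates divergent
genomes, taxonomies and error-bearing read mixtures of known
composition, so the full pipeline is testable without downloads.

## Worked example

```bash
sketchtax simulate -design design.yaml -out sim
sketchtax build -targets sim/references.fasta -taxonomy sim/taxonomy -out db -parts 2
sketchtax query -db db -reads sim/reads_1.fastq -reads2 sim/reads_2.fastq \
    -out result.tsv -abundance species
```

with `design.yaml` describing a 60/30/10% mixture of three sources plus
an in-database absent relative (2% divergent from the dominant taxon):

```yaml
seed: 5
genome_length: 50000
n_reads: 5000
read_length: 101
error_rate: 0.01
paired: true
taxa:
  - {name: cattle_like, divergence: 0.08, genus: bovids}
  - {name: buffalo_like, divergence: 0.02, genus: bovids, derived_from: cattle_like}
  - {name: pig_like, divergence: 0.10}
  - {name: chicken_like, divergence: 0.12}
composition: {cattle_like: 0.6, pig_like: 0.3, chicken_like: 0.1, buffalo_like: 0.0}
```

The query prints

```
reads=5000 classified=4320 unclassified=680 excluded_targets=0
```

and `result.abundance.tsv` holds the species-rank composition estimate:

```
taxid	rank	name	reads_est	percent
100	species	cattle_like	2609.2441	60.40
102	species	pig_like	1267.0000	29.33
103	species	chicken_like	442.0000	10.23
101	species	buffalo_like	1.7559	0.04
-1		unassigned	0.0000	0.00
```

The three present components are recovered within half a percentage
point, and the absent close relative — which shares ~72% of its k-mers
with the dominant source — picks up only 0.04%: reads ambiguous between
the two relatives go to their common genus and are redistributed by
observed subtree weight rather than being miscounted. Fractional
`reads_est` values come from that redistribution; `percent` is relative
to classified reads. The per-read `result.tsv` lists one row per read
with status, assigned taxon, best-range hit count and the retained
candidate list.

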