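# Methods

This note documents the models, rules and numerical choices behind
`magphage`, and what the synthetic cohort generator does and does not
emulate.

## The census model

A MAG is admitted when its completeness is ≥ 70% and its contamination
≤ 5%; medium quality means completeness in [70, 90], high quality
above 90%. A *lysogen* is a MAG carrying at least one retained
prophage. Because prophage recovery requires the full integrated
interval plus host flanks on a single contig, observed lysogeny is a
lower bound that degrades with bin quality; all prevalence statements
are therefore completeness-stratified.

### Viral-region handling

Region calls are consumed from an external caller's table when present.
Otherwise `detect_viral_regions` provides a transparent stand-in: genes
covered by any sliding window (default 10 genes) whose viral-annotation
fraction is ≥ 0.8 form candidate runs; maximal runs of ≥ 5 genes are
reported, trimmed to their first/last viral gene, and extended to the
contig end when the run touches the first or last gene (so a fully
viral contig carries no host flanks). Overlapping calls on a contig are
merged by union before extraction so prophage base counts are never
double-counted; touching-but-disjoint calls stay separate.

### Quality tiers and retention

Quality is scored from gene content over genes fully inside the region:
`non_viral_score` = non-viral genes / max(1, total), and the tier comes
from the viral-gene fraction — Complete ≥ 0.95 with both flanks
present, High ≥ 0.90, Medium ≥ 0.50, else Low; a region with no genes
is NotDetermined. These thresholds are configurable
(`QualityThresholds`); real external quality calls can be supplied via
the input tables instead.

Retention requires, in order: length strictly > 10,000 bp ("longer
than 10 kb" is read strictly; the boundary case 10,000 bp is rejected),
both host flanks (≥ 1 bp of contig on each side), gene evidence (≥ 1
viral gene OR zero non-viral genes — a disjunctive rescue, since a
conjunctive reading would make the second clause vacuous), and a
non-`none` caller label. The first failing rule is recorded as the
reason code, so retained + rejected always equals the input count and
relaxing any single threshold can only grow the retained set.

### vOTU clustering

Fragment-mapping ANI: the shorter sequence is cut into non-overlapping
500 bp fragments (a terminal remnant ≥ 100 bp is kept); each fragment
is aligned to the longer sequence by exact edit-distance dynamic
programming in infix mode (edlib). Fragments aligning at ≥ 0.70
identity count as aligned; ANI is their length-weighted mean identity
and coverage their fraction of the shorter sequence. Orientation is
fixed by (length, sequence) ordering, so the result is symmetric under
argument swap.

Clustering is greedy centroid clustering: sequences are visited in
decreasing-length order (ties by id ascending) and join the first
representative with ANI ≥ threshold and coverage ≥ 0.75, else found a
new cluster. Dereplication uses 99% ANI, species-like vOTUs 95%; the
75% coverage convention is applied at both levels (one convention,
configurable). The greedy order makes output independent of input
order, idempotent on representatives, and equal to a brute-force
full-matrix oracle (tested on hundreds of random instances). A 16-mer
prefilter skips alignment for pairs sharing < 2% of the shorter
sequence's 16-mers; any pair that could pass a ≥ 90% ANI / ≥ 75%
coverage gate shares far more, so the prefilter does not change
clustering results, only cost.

Genus-like vOTUs are a deliberately simplified stand-in for
protein-cluster network tools: viral genes of each species
representative are translated, clustered into families at ≥ 50%
amino-acid identity over ≥ 80% mutual length coverage (global
alignment), and genomes are connected when the hypergeometric
upper-tail probability of their shared-family count (given both profile
sizes and the family universe) is ≤ 0.05, i.e. edge weight
−log10 p ≥ 1.3. Genus vOTUs are connected components; genomes with no
proteins become singletons. This reproduces gene-sharing genus
behaviour without re-implementing a third-party tool and is labelled as
such.

Novelty against a catalog uses the species thresholds: a vOTU is
non-novel iff its representative clusters with ≥ 1 reference sequence.

### Lysogeny analytics

Completeness bins resolve the gap in the conventional "70–85; 86–95;
> 95" notation as [70, 85], (85, 95], (95, 100] — a contiguous
half-open cover (the first bin closed). Near-complete means strictly
> 95%. Family-level prevalence requires ≥ 30 near-complete MAGs;
cohort-group × family prevalence requires ≥ 5 MAGs per group;
undersized groups are still emitted, flagged `included=False`.

Early/Late categorization of infant MAGs compares the mean abundance
over available early timepoints (3 weeks, 3 months) with the mean over
late ones (6, 12 months): strictly greater → Early, strictly less →
Late, ties or a side with no data → Unassigned. The mean was chosen as
the simplest faithful reading of "difference in abundance"; swapping
the column groups provably flips the labels.

Spearman correlation uses mid-ranks with the t-distribution p-value
(n − 2 df); the rank-sum test is Mann–Whitney with exact enumeration
for n₁ + n₂ ≤ 12 without ties and the tie-corrected normal
approximation otherwise (both via scipy). Per-family abundance
comparisons require ≥ 5 MAGs per arm and are BH-adjusted across tested
families; raw p-values are reported alongside. The per-species minimum-n
rule is applied by analogy with the family rule and flagged in output.

### pAMG screening

A metabolic gene on a retained prophage is kept iff, in rule order:
the prophage's non-viral score is strictly < 0.25; its AMG score is in
{1, 2, 3}; ≥ 1 viral gene lies on each side within the prophage
("between at least 2 phage genes" is read as one per side — the
minimal reading consistent with "between"; genes outside the prophage
are not counted); its distance to the nearest prophage end is strictly
> 5,000 bp (applied to the trimmed prophage ends, since screening
operates on extracted sequences; configurable); and no
transposon-annotated gene lies within 5,000 bp ("at proximity" is
undefined upstream; the window matches the end-margin scale and is
configurable). AMG scores and non-viral scores are consumed as input
columns with defined semantics — this package does not annotate genes.
The CAZy strict subset keeps retained CAZy-labelled pAMGs on
Complete/High prophages with confirmation probability ≥ 90%
(strictly below 90 excluded); records lacking a confirmation value are
excluded and counted separately.

## The synthetic cohort generator

The generator emulates the data regime the census assumes, with every
prophage recorded as ground truth. Defaults (all configurable through
`SimulationConfig`):

| parameter | default | why |
|---|---|---|
| host_genome_length | 300,000 bp | desk-scale stand-in for multi-Mb genomes; keeps suites fast while leaving room for several prophages and realistic contig structure |
| host_gc | 0.45 | typical gut-bacterial GC |
| prophage_count_dist | Poisson(1.5) | gives ~22% prophage-free genomes and near-complete lysogeny around 60–75%, the range reported for gut MAGs; no literature distribution exists for per-genome counts, so this is a generator choice |
| prophage_length_dist | uniform 15–40 kb | typical temperate-phage genome sizes; all above the 10 kb retention floor |
| composition_shift | +0.08 GC | detectable compositional contrast between phage and host |
| viral/metabolic/transposon gene rates inside | 0.85 / 0.08 / 0.01 | mostly-viral cargo with occasional metabolic genes (AMG candidates) and rare transposons |
| viral_gene_rate_outside | 0.02 | background false viral annotation on host genes |
| gene length / spacing | uniform 600–1,200 bp / 60 bp | bacterial gene scale |
| completeness, contamination | uniform 70–100% / 0–2% | the admitted-MAG quality range |
| fragment_length_dist | uniform 30–80 kb | MAG-like contig sizes |
| boundary_jitter_sd, region_fnr, region_fpr | 200 bp, 0.1, 0.05/MAG | plausible caller noise; all zero in "noiseless" recovery tests |
| n_phage_templates | 25 (30% diverged variants at 8%) | a shared template pool creates true vOTU structure: copies of one template (2% per-copy substitutions) cluster as a species; diverged variants share protein families but not species-level ANI, giving genus structure |
| prophage_loss_bias / prophage_loss_tail | 1.0 / 0.05 | see below |

Prophages are contiguous insertions at distinct interior positions
(never overlapping, ≥ 1 bp of host between and around them). Contig cut
points are pushed off prophage intervals — an integrated prophage
assembles contiguously or not at all — so at 100% completeness every
planted prophage survives with flanks intact.

**Completeness-dependent, prophage-biased loss.** Contigs enter the bin
in descending random-priority order until the completeness target (in
bases) is met; the boundary contig is truncated to hit the target
exactly, so retained/source bases match the requested completeness to
within rounding. Prophage-bearing contigs draw their priority from the
bottom `prophage_loss_tail` (5%) of the range with probability
`prophage_loss_bias` (1.0): prophage loci sit in the hardest-to-recover
portion of the genome, as mobile and repeat-rich regions do in real
assemblies. Under uniform, completeness-independent loss, per-prophage
survival is roughly proportional to completeness and the
lysogeny–completeness coupling is much weaker than observed in real MAG
collections; the biased mechanism reproduces the observed regime — a
steep monotone prevalence gradient across the three completeness bins
(~0.31 / 0.51 / 0.61 at the defaults) and > 0.9 power for the
lysogen-vs-non-lysogen completeness rank-sum test at n = 200 MAGs.
Priorities and cut points are drawn from streams that do not depend on
the completeness target, so raising completeness always retains a
superset (survival monotonicity). A prophage survives fragmentation
only if its whole interval lies strictly inside one retained contig
(≥ 1 bp flank each side), matching the flanked-prophage retention rule.

Contamination is appended as foreign contigs (random sequence at GC
0.55, tiled with host-like genes) totalling ~contamination% of retained
bases. Abundance follows an early/late two-regime trajectory per infant
MAG (multipliers 2.0/1.4/0.35/0.2 or reversed, log-normal noise),
normalized per sample to one million copies; parental MAGs appear in a
single parental sample.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level sequencing error, assembly and
binning themselves (completeness is imposed, not estimated), real gene
calling or annotation error beyond flat rates, phage taxonomy,
integration-site biology (attachment sites, tRNA targeting), prophage
decay/domestication, and real abundance compositionality. Genome sizes
are desk-scale, so per-MAG prophage *fractions* run ~10× larger than in
real multi-Mb genomes; counts, prevalences and clustering structure are
the meaningful outputs, not the fraction's absolute value.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; FASTA headers carry ids
  only.
- Percentage formatting rounds half away from zero at the requested
  precision; a zero denominator prints `NA`.
- `pairwise_ani` on sequences with no aligning fragment returns
  ANI 0 / coverage 0; empty sequences raise.
- Greedy-order ties (equal lengths) break by id ascending; genus
  component labels are assigned by each component's smallest member, so
  all clustering output is deterministic under any input order.
- A rank-sum with all-tied pooled data falls back to the asymptotic
  method (exact enumeration assumes no ties).
- A region call with zero genes is tier NotDetermined and survives
  filtering only through the zero-non-viral rescue clause.
- Report text contains no timestamps; identical runs produce
  byte-identical reports. Thousands separators appear in the text
  report only, never in TSVs.

## Problem sizes

Test suites run on cohorts of 8–30 simulated MAGs (300 kb genomes) with
clustering oracles on ≤ 20 sequences of 1–2.5 kb; statistical
properties use interval-level cohorts of 200–3,000 MAGs, which replay
the planting/fragmentation arithmetic without sequence. The acceptance
script uses 60 full MAGs plus a 3,000-MAG interval cohort and 25 power
replicates at n = 200. These sizes were chosen so the whole suite runs
in minutes on one CPU while every mechanism is exercised end to end.

## Known limitations

- The annotation-density detector is a stand-in, not a re-implementation
  of any external caller; its defaults suit the generator's annotation
  rates and will need retuning for real annotations.
- Genus clustering by connected components merges chains; a modularity
  or clique-percolation step would split them but is out of scope.
- The hypergeometric edge model treats protein families as exchangeable;
  core-gene structure in real phages violates this.
- With contig-level loss granularity, near-complete bins (> 95%) still
  lose a visible share of prophages; the simulated near-complete
  prevalence (~0.6 before caller noise) sits below perfect recovery by
  construction.
- Per-species lysogeny comparisons apply the family-level ≥ 5 rule by
  analogy; output flags this so downstream users can re-filter.
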