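# Methods

`bypassnet` implements the computational pipeline of a genome-scale
bypass-suppression analysis of essential genes: isolating spontaneous
suppressors of essential-gene deletions, identifying the suppressor by
sequencing, and asking what distinguishes *dispensable* essential genes
(deletions that can be bypassed) from *core* essential genes. This note
records the models, the parameter choices, and what the synthetic data
do and do not establish.

## Genome-content calls from binned read depth

A chromosome gained or lost in a strain changes its relative read
depth: a disome in a haploid has twice the euploid depth, a trisome in
a diploid 1.5x. `call_chromosome_copy_numbers` therefore computes each
chromosome's mean bin depth, divides by a per-genome baseline, and sets
`copy = round(ratio * ploidy)`, with the overall ploidy supplied
externally (flow cytometry in practice).

* **Baseline** — the median of per-chromosome mean depths. The median is
  robust to one or two aneuploid chromosomes, which would drag a mean
  baseline toward them.
* **Rounding** — nearest integer, ties (x.5) rounding up. Calls whose
  scaled ratio sits 0.25 or more from the nearest integer are flagged
  `low_confidence` rather than silently rounded; such ratios arise from
  mosaic cultures or segmental changes, not clean aneuploidies.
* **Partial amplifications** — binary mean-shift changepoint
  segmentation of the bin-depth sequence with squared-error cost. The
  split penalty is `10 * sigma^2 * log(n)`, with `sigma` estimated
  robustly from successive bin differences (median absolute difference
  scaled by `sqrt(2) * 0.6745`). The factor 10 was calibrated so that
  flat chromosomes at 10% multiplicative depth noise produce no
  spurious segment in >= 99% of cases while planted segments of >= 3
  bins at +1 copy are recovered exactly in the noise-free limit.
  Segments are reported only when their rounded copy number differs
  from the chromosome-level call — a whole-chromosome gain belongs to
  the chromosome call, not the segment list.
* **Genome size** — `sum(length_c * copy_c)` over chromosomes (absolute
  copy counts) plus `extra copies x segment length` for partial
  amplifications, ignoring segments overlapping telomeric or
  rDNA-flagged regions, whose copy number varies for reasons unrelated
  to suppression.

Coordinates are 1-based inclusive for genes and half-open
`[bin_start, bin_end)` in bp for depth bins.

## Variant filtering and candidate nomination

Variant sites present in 5 or more strains are removed as pre-existing
background variants or systematic artifacts (`filter_recurrent_variants`,
`max_strains=4`). Candidate suppressor genes for one query are the genes
carrying a surviving nonsynonymous variant, flagged by four criteria:
unique nonsynonymous mutation (true by construction after filtering),
location in the genetically mapped suppressor locus when one is
available, recurrence across independent isolates of the same query,
and a functional connection to the query. Candidates are ranked by
(number of criteria met, relatedness priority, gene id).

Suppressor loci are mapped from genome-ordered SGA interaction scores:
array deletion alleles genetically linked to the unmarked suppressor
produce a collinear run of reduced double-mutant colony sizes.
`detect_linkage_locus` replaces the visual inspection used in practice
with an explicit rule — the maximal within-chromosome run of >= `window`
(default 10) consecutive genes at or below a score threshold, the run
with the lowest mean winning ties. The threshold should be set from the
null score distribution of the screen (e.g. its 5th percentile).

## Functional relatedness

The compendium holds five standards: protein complexes, pathways, a
scored coexpression network (coexpressed means score strictly > 1),
subcellular localization, and biological-process terms. Each pairwise
predicate is tri-state: *true*, *false*, or *unknown* when either gene
lacks data for that standard. Two conventions follow from this:

* In the ranking code, unknown counts as 0 — missing data must never
  promote a gene.
* In enrichment, pairs unknown for a standard are excluded from both
  numerator and denominator: only pairs with data for both genes are
  evaluable.

The ranking of genes on an aneuploid chromosome is strictly
lexicographic — cocomplex (8) > copathway (4) > coexpressed (2) >
colocalized (1) — implemented as a descending sort of the resulting
4-bit integer. A gene cocomplex with the query outranks any gene with
every lower-priority relation but not that one. Ties share the mean
(fractional) rank for evaluation; display order within ties is stable
by gene id. The shared-process predicate participates in mechanism
classification (same complex > same pathway > same process > other
functional > unrelated/unknown) and enrichment but not in the ranking
code. The random baseline in `evaluate_ranking` draws uniform orderings
with the same fractional-rank convention and compares rank samples with
a two-sided Mann-Whitney U test.

## Saturation analysis

Per query, isolation experiments are randomly split one-per-screen into
four artificial screens (queries with fewer experiments dropped, surplus
experiments re-subsampled on every permutation); screen k counts the
discoveries not seen in screens 1..k-1. Means over 1,000 permutations
form the discovery curve for either endpoint (dispensable query genes,
or query-suppressor pairs with the suppressor identified). A
logarithmic model `C(k) = a + b ln k` is least-squares fitted to the
cumulative means — fitting the cumulative rather than the per-screen
differences carries the same information with better conditioning. The
logarithmic model is unbounded, so any "fraction discovered" is
reported against an explicit horizon (`C(K)/C(horizon)`); a bounded
exponential-saturation alternative `C(k) = S(1 - e^{-lambda k})` is
fitted alongside for sensitivity, and its `S` is the implied pool size.

## Enrichment statistics

Fold enrichment of a standard among observed query-suppressor pairs is
the ratio of evaluable-pair fractions, observed vs a background of all
(query, genome gene) pairs minus the observed ones; significance is
Fisher's exact test on the 2x2 of origin x predicate. Fisher tests are
two-sided by the point-probability rule unless stated; sidedness is
recorded in every result because conventions differ. No
multiple-testing correction is applied by default (results carry raw
p-values). Group property comparisons use Fisher (binary) and
Mann-Whitney U (continuous) with the AUROC — the rank-sum statistic
rescaled to [0, 1] — as effect size; a feature constant in both groups
is flagged uninformative. The permutation test for relatedness of
co-occurring suppressor pairs resamples the same number of pairs from
the universe and uses the add-one empirical p-value, which can never be
exactly zero.

## Screen scoring

Colony areas are normalized per plate by dropping border positions
(first/last row and column), dropping manually flagged rough colonies,
averaging replicates per strain and condition, dividing by the
wild-type mean of that condition, and averaging across conditions.
Overexpression screens are scored per array gene as
`z = (median_gene - median_empty) / sd_empty` where `sd_empty` is the
sample standard deviation of empty-vector colony sizes; a hit requires
`z > 1.5` and `p < 0.05`. The default p-value is the two-sided normal
tail of z — the simplest reading of a Z-score-associated p — with an
empirical alternative computed from the centred empty-vector
distribution. Genes hit in three or more screens are frequent flyers
and are removed everywhere; plasmids overexpressing the query itself
are excluded from final hits but kept in a control report, since
self-overexpression rescue is the expected positive control.

## Dispensability classification

A random forest (default 1,000 trees) is trained on gene features to
separate dispensable from indispensable essential genes. Class
imbalance is handled by undersampling the majority class to the
minority size in each of `n_replicates` (default 5) training draws;
evaluation uses only rows the forest did not train on — out-of-bag
predictions for sampled rows plus ordinary predictions for the
undersampled-away rows — and the reported AUROC is the replicate mean
with its min-max range. Per-feature ablation retrains without one
feature at a time under the same protocol. On the strongly planted
synthetic features the held-out AUROC exceeds 0.9; this validates the
training/evaluation machinery, not any claim about real data, where
feature effects are far weaker.

Rule-based classifications:

* **Core-essential list** — experimentally bypassed genes are
  dispensable essential; untested genes are split at prediction score
  0.5 (strictly above: dispensable, strictly below: core); genes that
  would be core are reclassified dispensable when a bypass suppressor
  is described in the literature. A score exactly at 0.5 leaves a gene
  unclassified: the boundary is handled conservatively because the
  split is defined by strict inequalities.
* **Cell-line essentiality** — a gene is essential in a cell line when
  its dependency score is strictly below tau = -0.7 (CERES scale; more
  negative = more essential). Essential in strictly more than 90% of
  lines: indispensable; strictly fewer than 10%: nonessential;
  otherwise context-dependent. The sensitivity thresholds tau = -0.5 /
  lo = 0.50 pass through the same parameters. Exact boundary fractions
  fall in the non-extreme class.
* **Median-centred Z normalization** — continuous features of
  context-dependent genes are normalized as
  `(x - median(reference)) / sd(reference)` against the indispensable
  reference group; only the centring statistic is robustified, the
  spread stays the sample standard deviation.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed); per-entity
streams are derived by hashing (seed, entity key), so enlarging a
cohort never perturbs existing strains. Defaults encode the cohort
structure the pipeline is designed for:

* ~18% of genes essential; 16 unequal, size-ordered chromosomes;
  chromosome ends flagged telomeric and one internal rDNA locus.
* 17% of query genes dispensable; 5 isolation experiments per query
  with detection probability 0.5 per experiment.
* Mechanism mix per suppressor strain: snp 0.51, aneuploidy 0.25,
  wgd 0.17, partial amplification 0.07 — about half of strains carry
  genome-content changes, with whole-genome duplication the largest
  single class among them. The aneuploidy/partial split within that
  half is our choice.
* Passenger variants: Poisson with mean 2 nonsynonymous-biased
  passengers per strain, plus the planted suppressor variant for SNP
  mechanisms — a median of 2-3 unique nonsynonymous variants per
  strain. Only a median is known for the real cohort; Poisson is our
  choice of count law.
* Functional coupling: with probability 0.7 the planted suppressor is
  functionally related to its query, the tier drawn as 40% cocomplex,
  30% copathway, 20% coexpressed-only, 10% colocalized-only, falling
  through to lower tiers when the query has no partner at the drawn
  tier. This puts the functionally-explained fraction of pairs near
  70%, with same complex/pathway pairs around 20% at the pair level.
* Depth profiles: expected bin depth `mean_depth * copy / ploidy`
  (default 30x), multiplicative Gaussian noise at CV 0.1; a bin takes a
  segment's copy number when at least half of it lies inside the
  segment. Partial amplifications span at most ~40% of their
  chromosome, keeping them genuinely partial.
* Screens: colony sizes are simulated directly in normalized units
  (post-plate-normalization); raw plate geometry appears only in the
  normalization fixtures. Empty-vector controls default to 64 colonies
  per screen, reflecting the many control positions of a 1536-colony
  array; frequent flyers are shifted in every generated screen.
* Feature tables plant the observed effect directions: dispensable
  genes enriched for paralogs and membrane proteins, depleted for
  complex members, with lower coexpression degree, plus zero-effect
  negative-control features. Effect sizes are deliberately strong so
  recovery tests are sharp.
* Dependency matrices draw per-gene means with between-gene jitter
  inside each group, so non-planted genes spread over the nonessential
  and context-dependent classes; planted indispensable-like genes fall
  below -0.7 in > 90% of lines.
* Fitness of suppressor strains is drawn from a Beta(5, 2) scaled to
  [0.3, 1]; no empirical distribution is available for this quantity
  and it is flagged unvalidated.

What passing the synthetic suites shows: the algorithms recover planted
structure under the stated noise and coupling assumptions. What it does
not show: performance on real cohorts, where annotation standards are
incomplete and biased, effect sizes are weaker, variants cluster in
mutational hotspots, and depth profiles carry GC and mappability
artifacts none of which are simulated.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
genomes of 300-4,000 genes, cohorts of 40-150 queries, 1,000
permutations for saturation curves, 200 replicates for null-calibration
checks, and 100 seeded screens; these sizes were chosen so that every
stage's statistical check retains its intended resolution while the
whole pipeline remains quick to re-run.

## Known limitations

* The changepoint penalty assumes roughly homoscedastic multiplicative
  noise; depth waves (GC, replication timing) would need pre-correction.
* The mechanism taxonomy collapses finer published categories (e.g.
  mRNA- or protein-degradation routes) into "other functional".
* Strict lexicographic ranking follows the procedural definition; a
  real-valued weighting of the four predicates is not reconstructable
  from the available description and is not attempted.
* Whether reported top-k ranks should use fractional or best-case tie
  ranks is ambiguous; both are computable from the ranking table
  (`fractional_rank` vs `rank`).
* The saturation "fraction discovered" depends on the horizon by
  construction; no single headline number is produced.
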