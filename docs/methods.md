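# Methods

## The problem and the model

Most trait-associated variants from genome-wide association studies lie in
the non-coding genome, where the causal mechanism is assumed to run through
cis-regulatory elements: a variant alters the binding of a DNA-binding
factor, which changes enhancer activity and, downstream, gene expression.
Six assay-derived markers are commonly used to annotate active regulatory
elements — open chromatin from DNase-seq (DHS) and ATAC-seq, H3K27ac
histone acetylation, DNA-binding factor occupancy from ChIP, DNase
footprints (short protected regions inside DHS indicating direct factor
binding), and enhancer RNA (eRNA, short divergent transcripts at active
enhancers). This package benchmarks every combination of those markers for
its *precision* in flagging functional variants, using molecular QTL
(molQTL) sets as truth: variants with measured allelic effects on factor
binding (bQTL), reporter-assay expression (raQTL), or chromatin
accessibility (caQTL).

For a candidate variant set and a feature combination, a variant is a
*member* when it overlaps **every** feature in the combination (AND
semantics; the alternative OR reading would make predicted-negative counts
shrink with combination order, the opposite of what member filtering does).
Against a truth set,

```
precision = TP / (TP + FP)      recall = TP / (TP + FN)
```

with TP = members in the truth set. Truth matching is by variant id (rsID),
not coordinate, since molQTL compendia are collapsed to unique rsIDs.
Precisions are standardized per truth set to Z-scores using the
*population* SD (a descriptive standardization across a fixed, fully
enumerated set of combinations), and the combination × truth-set Z matrix
is clustered hierarchically with Euclidean distance and Ward-D2 linkage
(scipy's `ward` on raw observations, which matches R `hclust(...,
method="ward.D2")` on Euclidean distances; verified against Rscript in the
test suite). Undefined precision (no members) propagates as missing, never
as 0, so empty combinations cannot fake cluster structure.

## Coordinate conventions

Tracks are BED-style 0-based half-open intervals. Variants are 1-based and
occupy `[pos-1, pos)` for overlap; the conversion lives in one function
(`genome_io.variant_points`). Merging requires ≥ 1 shared base pair —
book-ended intervals stay separate (equivalent to `bedtools merge -d -1`,
and cross-checked against bedtools in the tests). Signed distances count
the bases strictly between a point and the nearest interval, positive when
the interval lies to the genomic right; ties resolve to the right. DHS
have no strand, so "upstream/downstream" of a summit is genomic
left/right.

Genomic-location annotation assigns one category per variant with the
fixed precedence promoter-TSS > 5'UTR > 3'UTR > exon > intron > TTS >
intergenic, a promoter window of −1000/+100 bp around the TSS
(strand-aware) and a ±100 bp TTS window; these mirror the common
HOMER-style defaults, but the exact tie-breaking of that tool is not
reproduced. The gene model is read from a refFlat-style transcript TSV.

## The random-subset null (fold change)

Fold change expresses a combination's precision relative to the precision
of the candidate set with no feature filter. The null model draws
`sample_size` variants from a common-SNV pool (MAF ≥ 1%) without
replacement, 100 times by default, and records per-iteration fold changes;
the global seed expands to per-iteration seeds through a counter, so
results do not depend on chunking. Because iterations resample a *fixed*
pool, their mean converges to the pool's realized fold change, which
itself fluctuates around 1 (under label independence) with a
binomial-scale SE that iteration scatter cannot see. The result therefore
carries both the iteration SD and the pool-level delta-method SE

```
Var(fold)/fold² ≈ (1−p)/p · (1/m − 1/n)
```

(p = truth rate, m = pool members of the combination, n = pool size); any
calibration claim must combine the two. Iterations where a combination has
no members contribute missing values and are excluded from the mean.

## Spike-in evaluation

A curated positive set is diluted with random decoys to a fixed prior
(defaults 210 positives + 4000 decoys ≈ 0.05, ten permutations). Positives
stay fixed; only decoys are re-drawn, without replacement. Decoys that are
genuinely functional still count as negatives, a conservative bias that
deflates measured precision. Two analytic anchors hold exactly: an
all-pass signature has precision equal to the prior and recall 1; a
signature containing every positive and no decoy has precision and
recall 1.

## Classifier and feature importance

MolQTL membership (union of the three assays) is predicted from the six
binary overlap features with a random forest (500 trees, default depth)
after downsampling both classes to the minority size, then a stratified
75/25 train/test split. The reported `predictive_value` is held-out
*accuracy* (flagged as such in all outputs) with AUROC alongside, because
the bare term is ambiguous for a balanced binary task.

Importance uses exact interventional Shapley values: with m ≤ 16 binary
features, the model output over all 2^m feature patterns is precomputed in
one batch and every coalition is enumerated against the empirical
background distribution of training patterns, so the attribution is exact
— no sampling — and satisfies additivity (`base + Σφ = f(x)`) to float
precision, which the tests assert. The per-feature summary is the mean
attribution over samples where the feature is present; positive values
push toward the positive class.

## LD expansion and prioritization

Lead variants are expanded through a pre-fetched LD table: linked variants
with R² ≥ 0.7 (inclusive, following the TopLD-style query convention; the
stricter exclusive reading is a flag away), unsigned distance ≤ 500 kb,
and MAF ≥ 1%. Every lead is always retained; duplicate ids keep the
maximum-R² provenance. Prioritization keeps variants overlapping **both**
DNase footprints and eRNA and reports the reduction fold
|input|/|prioritized|. Per-trait precision/recall summaries across ≥ 2
traits use a normal-approximation 95% CI (mean ± 1.96·SE across traits);
the CI method is a package choice.

## The synthetic-data generator

The generator produces self-contained inputs with the structural features
the analysis relies on; its defaults are the package's study conditions.

* **Genome**: 3 chromosomes × 10 Mb — large enough for stable coverage
  targets, small enough for seconds-scale runs.
* **Tracks**: interval lengths are log-normal (median, dispersion σ of the
  log; the field reports medians, so the dispersion is a modeling choice).
  Coverage targets per marker follow the qualitative hierarchy of merged
  multi-biosource compendia: ATAC 0.60 > H3K27ac 0.50 > ChIP 0.25 >
  DHS 0.12 > footprints 0.035 > eRNA 0.02. Intervals accumulate in batches
  until the merged coverage meets target (raising an error when the
  placement region saturates), so realized coverage lands within a few
  percent of target. DHS intervals get a summit (uniform in the central
  third) and a consensus core (log-normal, median 37 bp). Footprints nest
  inside a parent DHS near its summit with probability 0.9 (Gaussian
  offset, sd 40 bp); eRNA is placed around summits (sd 300 bp); ChIP and
  the broad marks are partially summit-biased. Each candidate interval is
  assigned to ≥ 1 of the marker's biosources, so the biosource union
  reproduces the merged master exactly.
* **Variants**: a functional fraction (default 0.25) of 2000 GWAS-style
  variants lands inside the footprint∩eRNA signature with probability 0.8
  (the planted enrichment), the rest uniformly. Each functional variant
  enters the three molQTL sets through a primary assay drawn from an
  affinity distribution with per-assay detection probabilities, plus a
  cross-assay overlap control (default 0.05) that keeps the three sets
  near-disjoint, mirroring the minimal overlap seen between real assay
  compendia. A 5000-variant common-SNV pool (MAF ≥ 1%) follows the same
  rules with its own functional fraction.
* **Planted-precision mode**: a designated fraction of variants is placed
  uniformly *inside* the signature and is functional with probability
  exactly π, all others strictly outside, and detection is forced to 1 —
  so the signature's realized precision is a Binomial(n, π) proportion and
  parameter recovery can be judged against an exact binomial CI.
* **LD blocks**: each lead gains linked variants within 500 kb with
  R² ~ U(0.2, 1); in recovery-test mode exactly one linked variant per
  block is planted inside the signature (R² ≥ 0.75) and everything else
  outside it, so expansion + prioritization must return exactly the
  planted variants.
* **Determinism**: one integer seed drives every draw through named
  substreams; identical configs give byte-identical output files.

What the generator does *not* emulate: sequence content, realistic LD
decay, cell-type-specific track structure, overlapping trait
architectures, or the heavy-tailed size distributions of real compendia.
Passing tests therefore demonstrate that the machinery is correct and
well-calibrated on data with known structure — not that the headline
numbers of any particular real-data analysis are reproduced, which would
require the external compendia themselves.

## Numerical and statistical choices

* Precision with an empty denominator is missing (NaN), and missing values
  are excluded from Z-scores, cluster input, and trait means.
* Z-scores use population SD; zero variance raises instead of silently
  producing zeros.
* Iteration/permutation SDs are sample SDs (ddof = 1), matching
  error-bar conventions.
* The null-calibration and parameter-recovery tests run at a 2 × 2 Mb
  genome with 2000-variant samples — sizes chosen so that every feature
  combination retains enough members for its confusion counts to be
  informative while the full suite stays fast.
* Rank claims about the top combination are evaluated on precision pooled
  across seeds: the expectation gap between footprint∩eRNA and the
  runner-up (eRNA plus a broad mark) is only ~3 single-seed SEs, so
  single-seed ranks can swap; pooling across 5–10 seeds makes the ranking
  decisive.

## Known limitations

* `annotate_variants` scans transcripts linearly per chromosome; adequate
  for desk-scale gene models, not for a full transcriptome at millions of
  variants.
* Exact Shapley enumeration is limited to ≤ 16 binary features by design;
  continuous features are rejected.
* The LD generator draws R² independently of distance; it validates the
  filtering logic, not population-genetic structure.
* Book-ended-interval merge semantics differ from `bedtools merge`'s
  default (`-d 0`); use `-d -1` when comparing externally.
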