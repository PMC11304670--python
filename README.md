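# finder

**F**unctional SNV **I**de**N**tification using **D**Nase footprints and
**e**nhancer **R**NA: benchmarking and prioritization of functional
non-coding variants.

Most GWAS hits fall in the non-coding genome, and annotating them with
markers of active regulatory elements (open chromatin, H3K27ac, factor
binding) still predicts poorly which variants actually change regulatory
activity. This package is for regulatory-genomics analysts who want to
(1) benchmark every combination of six active-element markers — DHS, DNase
footprints, ATAC, ChIP, eRNA, H3K27ac — for precision against molecular-QTL
truth sets (bQTL / raQTL / caQTL), and (2) apply the winning
footprint∩eRNA signature to shrink GWAS and LD-expanded candidate sets to
a small, high-precision subset for functional follow-up.

The core statistic is precision (positive predictive value) of a feature
combination *C* against a truth set *T* over a candidate set *V*:

```
members(C) = { v ∈ V : v overlaps every feature in C }        (AND)
precision  = |members(C) ∩ T| / |members(C)|
recall     = |members(C) ∩ T| / |V ∩ T|
```

Precisions are standardized per truth set (Z-score, population SD),
clustered with Ward-D2 linkage, compared against random-SNV subsets as
fold change (mean ± SD over 100 draws), corroborated by a balanced
random-forest classifier with exact Shapley feature importance, and
stress-tested by a spike-in design that dilutes curated positives with
random decoys to a fixed ~0.05 prior. Every stage runs on a self-contained
synthetic-data generator with planted structure, so the whole pipeline is
testable without any external download. See `docs/methods.md` for the
model, parameters, and limitations.

## Worked example

Generate a synthetic dataset (two 2-Mb chromosomes, seed 11), benchmark
all marker combinations, and prioritize LD-expanded variants:

```bash
finder simulate --seed 11 --outdir demo            # tracks + variants + LD
finder benchmark --variants demo/gwas.tsv \
    --truth bQTL=demo/molqtl_bQTL.tsv --truth raQTL=demo/molqtl_raQTL.tsv \
    --truth caQTL=demo/molqtl_caQTL.tsv \
    --tracks footprint=demo/tracks/footprint.merged.bed \
    --tracks eRNA=demo/tracks/eRNA.merged.bed \
    --tracks DHS=demo/tracks/DHS.merged.bed ... \
    --out-prefix demo/bench
finder expand-ld --leads demo/gwas.tsv --ld-table demo/ld.tsv \
    --out demo/expanded.tsv
finder prioritize --variants demo/expanded.tsv \
    --footprints demo/tracks/footprint.merged.bed \
    --erna demo/tracks/eRNA.merged.bed --out demo/prioritized.tsv
```

On this dataset the benchmark's top two-way combinations by mean precision
across the three molQTL sets are:

```
eRNA+footprint    0.229
DHS+eRNA          0.227
ChIP+eRNA         0.225
```

— the footprint∩eRNA signature leads, and every high-precision combination
contains eRNA and/or footprints, while broad marks alone sit far lower.
The prioritization step prints

```
2000 leads -> 2133 variants; wrote demo/expanded.tsv
2133 -> 411 variants (reduction fold 5.2); wrote demo/prioritized.tsv
```

i.e. LD expansion grew the candidate set, and requiring co-localization
with both footprints and eRNA cut it ~5-fold (the reduction is much
steeper when, as in real data, the signature covers a smaller genome
fraction than this compact demo genome allows). In the generator's
LD-recovery mode, the prioritized set contains exactly the one planted
functional variant per LD block.

The same machinery is available as a library:

```python
from finder import SimConfig, simulate_tracks, simulate_variants, run_benchmark
cfg = SimConfig(seed=11)
tracks = simulate_tracks(cfg)
vs = simulate_variants(cfg, tracks)
result = run_benchmark(vs.gwas, list(tracks.merged.values()),
                       list(vs.molqtl.values()))
result.zscores        # combinations x truth sets, mean 0 / SD 1 per column
result.clusters       # Ward-D2 cluster label per combination
```

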