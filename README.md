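# slicepattern

Spatial gene-expression pattern analysis for cryosliced embryos. An embryo is
cut into ~25–30 equal slices along the anterior–posterior axis and each slice
is expression-profiled (FPKM); this package compares the resulting per-gene
spatial profiles across genotypes using the 1-D Earth Mover's Distance (EMD),
classifies patterns, scores differential responses to pairs of mutants, and
tests for transcription-factor ChIP-binding enrichment — all exercised
end-to-end on synthetic cohorts with known ground truth.

## Modules

| module          | what it does |
|-----------------|--------------|
| `synthetic`     | parametric AP patterns (gradients, Gaussian domains, stripes), genotype effect operators (loss, uniformise, shift, ectopic gain, level scale), slicing with lognormal noise and QC failures, truth tables, synthetic TSS/peak/enhancer tracks |
| `io_formats`    | expression + metadata TSVs, BED peaks/enhancers, TSS tables |
| `profiles`      | QC-slice imputation, max-normalisation, unit-mass spatial distributions, exact CDF-based EMD, a transportation-LP reference oracle, adjacent-slice similarity curves |
| `pattern_stats` | pattern classification (low / uniform / ambiguous / patterned), transition tables, cross-replicate pattern change, the delta-D differential-response score, top-20% change flags and co-change tests, top-changed averages, EMD hierarchical clustering, 1.5-fold level-response counts |
| `enrichment`    | peak-to-gene assignment (±10 kb of TSS), enhancer→nearest-TSS mapping, per-TF chi-squared enrichment (category and delta-D designs), combinatorial binding trends, binding-signature KS tests |
| `cli`           | `slicepattern` command: orchestrated stages with YAML config, deterministic flat-TSV outputs, manifest |

## CLI

```bash
slicepattern report --seed 1                 # full synthetic run into ./slicepattern_out
slicepattern report --config config.yaml     # with explicit paths/thresholds
slicepattern simulate|distances|classify|deltad|enrich|cluster|heatmaps --config config.yaml
```

A config YAML may set input paths (`expression`, `metadata`, `peaks`, `tss`,
`enhancers`), `outdir`, `seed`, genotype roles (`wt_genotype`,
`m1_genotype`, `m2_genotype`), threshold overrides, and a `simulate:` block of
cohort parameters (`n_genes`, `genotypes`, `timepoints`,
`replicates_per_timepoint`, `slice_count_range`, `noise_sigma`,
`qc_fail_rate`, `effect_probability`). When no expression path is given the
pipeline simulates a cohort first. Outputs are flat TSVs plus
`manifest.json`; identical config + seed reproduce byte-identical files.

Default thresholds: genes count as expressed at ≥15 FPKM in at least one
slice; patterns are uniform below EMD 0.04 to a flat distribution and
patterned above 0.08; heatmap normalisation divides by the per-embryo maximum
or 10 FPKM, whichever is greater; change flags take the top 20% of each EMD
distribution; delta-D enrichment compares the top 50 scoring genes against the
200 closest to the median (so it needs a few thousand scored genes — the
stage is skipped with a warning on small cohorts).

## Conventions

- Slice `i` of `N` covers `[i/N, (i+1)/N)` of embryo length, anterior first;
  profiles become unit-mass point distributions at slice centres
  `(i+0.5)/N`, so EMD is in `[0, 1]` and a one-slice shift ≈ `1/N`.
- Genomic intervals are 0-based half-open (BED native); TSS positions are
  1-based points, converted at the boundary.
- Expression column labels are `EMBRYOID_sliceNN` (NN 1-based,
  anterior→posterior), contiguous per embryo; FPKM written with 6
  significant digits.
- QC-failed slices are imputed as the mean of the nearest usable slice on
  each side (nearest-neighbour copy at the embryo ends).

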