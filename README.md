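# metaboqc

Preanalysis quality control for population-scale metabolomics data.

Curated metabolomics datasets (NMR or LC/GC-MS, typically hundreds to
thousands of samples and features) need a characterization and filtering
pass before any statistical analysis: samples of poor quality and features
with unfavorable statistical properties must be identified, and properties
that drive downstream choices (missingness, skew, correlation structure,
batch effects, power) must be reported transparently. `metaboqc` implements
that workflow as a library plus a command-line tool: it reads a plain-text
abundance matrix (with optional sample metadata and feature annotation),
optionally median-normalizes across batches, computes sample- and
feature-level summary statistics, applies an ordered, user-parameterized
exclusion pipeline, quantifies batch effects, and writes summary tables, an
exclusion log, a self-contained HTML report and a per-feature plot document.

## The statistics at the core

For a samples × features matrix **X** with missing entries:

- **Missingness** — per sample and per feature, the fraction of absent
  entries. Sample missingness is also computed excluding *xenobiotics*
  (exogenous compounds whose absence usually means true non-exposure) and,
  optionally, *derived* measures (ratios/sums of other features).
- **Total sum abundance (TSA / total peak area)** — per sample, the sum of
  z-transformed feature values recentred by the absolute value of the global
  standardized minimum, computed over all features and again over complete
  (no-missing) features; a proxy for total measured concentration.
- **Extreme-value counts** — a cell is flagged when
  |x − median(feature)| > k · IQR(feature), k = 5 by default.
- **Feature descriptives** — n, mean, SD (n−1), adjusted Fisher–Pearson
  skew, CV, and Shapiro–Wilk W on raw and log10 scales.
- **Feature reduction** — complete-linkage hierarchical clustering on the
  distance 1 − |Spearman ρ| (pairwise-complete), cut at a user height
  (default 0.5); each cluster's least-missing member is its *representative*
  and the cluster count is the effective number of features.
- **PCA** — on the median-imputed, z-transformed representatives; retained
  component count by the scree acceleration factor (maximum second
  difference of the eigenvalues, minimum 2) and by parallel analysis;
  samples more than t SD from the mean on the retained components are
  outliers.
- **Filtering**, in order: extreme (≥80%) sample then feature missingness;
  user-threshold (≥, default 20%) sample then feature missingness
  (xenobiotics exempt throughout); TSA over complete features (>5 SD);
  PC outliers (>5 SD). Every step is logged with thresholds and removed ids.
- **Batch effects** — η² = SS_between/SS_total per batch variable
  (one-way ANOVA), plus type-II η² from an additive multi-variable model.
- **Power** — two-sample t (noncentral t, unequal n allowed) and general
  linear model F (noncentral F) power at effective sample sizes implied by
  the observed missingness.

## Worked example

A small synthetic dataset ships in `examples/fixture/` (80 samples × 24
features, three planted correlation blocks, two batches, one planted
whole-profile outlier sample, one planted PC-outlier sample, xenobiotic and
derived features). Run the full pipeline with the example parameter file:

```bash
metaboqc run \
  --matrix examples/fixture/abundance_matrix.tsv \
  --sample-meta examples/fixture/sample_metadata.tsv \
  --feature-meta examples/fixture/feature_annotation.tsv \
  --params examples/params.txt \
  --outdir out/
```

which prints:

```
samples: 80 -> 77
features: 24 -> 24
  extreme_sample_missingness (>=80%): removed 0 sample(s)
  extreme_feature_missingness (>=80%): removed 0 feature(s)
  sample_missingness (>=20%): removed 1 sample(s)
  feature_missingness (>=20%): removed 0 feature(s)
  sample_tsa (>5SD): removed 1 sample(s)
  sample_pca_outliers (>5SD): removed 1 sample(s)
effective number of features (clusters): 3
retained components: acceleration factor n=2, parallel analysis n=0
outputs written to .../out
```

Reading: one sample exceeded the 20% missingness threshold; the planted
whole-profile outlier left at the TSA step and the planted PC outlier at the
PCA step; no feature crossed a missingness threshold (the two xenobiotics
are ~85% missing but exempt); clustering found the three planted blocks
(effective number of features = 3); the representatives are nearly
independent, so parallel analysis retains no component and outlier detection
uses the acceleration-factor floor of two. `out/` then contains the raw and
filtered matrices, the four summary tables, `exclusion_log.tsv`,
`run_log.txt`, `qc_report.html` and `feature_plots.pdf`. Re-running with the
same parameter file reproduces every file byte for byte.

### Parameter file

Flat `key=value` lines, `#` comments; the key names are defined by this
package (see `examples/params.txt`): `feature_missingness_max`,
`sample_missingness_max`, `tsa_sd_threshold`, `outlier_iqr_multiplier`,
`pca_outlier_mode` (leave | to_na | winsorize), `tree_cut_height`,
`pc_sd_threshold`, `exclude_derived`, `batch_normalization_column`,
`rng_seed`. Missing keys take the defaults above; unknown keys are rejected.

### Output table columns

Sample summary: `missingness_all`, `missingness_excl`, `tsa_all`,
`tsa_complete`, `outlier_count`, `PC1`..`PC10`. Feature summary:
`missingness`, `n`, `mean`, `sd`, `skew`, `cv`, `w_raw`, `w_log10`,
`outlier_count`, `independent_features_binary` (1 = cluster representative).

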