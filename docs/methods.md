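# Methods

This note records the statistical procedures `metaboqc` implements, the
conventions chosen where several were defensible, and what the synthetic
data used by the test suite does and does not establish.

## Data model

The abundance matrix is samples × features, non-negative reals with
missing entries; the recognized missing tokens are the case-sensitive set
`{"NA", "", "NaN"}` (matching common R export conventions). Feature
annotation carries two flags. *Xenobiotics* are exogenous compounds: a
missing value usually encodes true non-exposure rather than a technical
failure, so they are excluded from sample-missingness calculations and are
never removed by missingness filters. *Derived* measures are ratios or
sums of other features; because a missing parent makes the derived value
missing, they bias missingness and correlation structure, and the user can
exclude them from all summary computations (`exclude_derived`). When they
are excluded from computations they also pass through the feature filters
untouched, so the exported filtered matrix still contains them and the
user can decide downstream.

## Summary statistics

**Missingness** is the fraction of absent entries per sample (over
non-excluded features) or per feature (over all samples).

**Total sum abundance (TSA).** Each retained feature is z-transformed over
its non-missing entries (SD with n−1). Let m be the minimum over all
standardized retained entries; every entry is shifted by |m| so all
contributions are non-negative, and the per-sample sum is taken, skipping
missing entries. Two variants are produced: over all retained features
(which is by construction correlated with missingness, since absent
entries contribute nothing) and over complete features only; the latter is
the one used for exclusions. The recentring uses the *global* standardized
minimum rather than a per-feature minimum — the alternative reading would
make each feature's minimum contribute exactly zero and change only the
offset, not the ordering, of TSA; the global convention is kept and
documented here. Zero-variance features are dropped from TSA with a
warning. Xenobiotics (and derived features, when configured) are excluded
from TSA: presence/absence compounds do not measure total concentration.

**Extreme values.** A cell is flagged when |x − median| > k·IQR of its
feature (non-missing entries, linear-interpolation quantiles; k = 5 by
default). If IQR = 0 any value off the median is flagged, hence an
all-equal feature yields no flags. Missing cells are never flagged.

**Descriptives.** SD uses the n−1 denominator; skewness is the adjusted
Fisher–Pearson standardized third moment (the common default across the
major statistical ecosystems — the estimator choice only matters at small
n); CV = SD/mean when the mean is nonzero. With fewer than 2 (SD) or 3
(skew) observations the statistic is missing.

**Normality.** Shapiro–Wilk W on raw values and on log10 of the positive
values (non-positive entries are treated as missing for the transformed
variant rather than offset by an arbitrary pseudo-count). Above n = 5000
the statistic is computed on a seeded random subsample of 5000, keeping
runs deterministic under the configured seed.

## Batch normalization

When a batch column is configured, each feature is scaled multiplicatively
per batch by (overall feature median)/(batch feature median) *before* any
summary or filtering step, so every batch's within-batch median equals the
feature's overall median. Scaling to the overall median (rather than to 1)
preserves the abundance scale that TSA sums. Batch-feature pairs with a
zero or undefined median are left unscaled with a warning. The operation
preserves the missingness pattern and is idempotent to numerical
precision. Normalizing first matters in practice: uncorrected
multiplicative batch shifts attenuate between-feature rank correlations
and can fragment correlation clusters.

## Feature reduction and PCA

Features enter the reduction stage if they are variable, have ≤ 20%
missingness, and are neither xenobiotic nor (when configured) derived.
Pairwise Spearman correlations use pairwise-complete observations; pairs
sharing fewer than 3 observations get distance 1 with a warning. The
distance 1 − |ρ| treats strong negative correlation as redundancy.
Complete-linkage agglomeration is cut statically at the configured height
(default 0.5, i.e. |ρ| = 0.5): clusters are the subtrees whose merge
heights are all below the cut. Each cluster's least-missing feature is the
representative, ties broken by input column order (a deterministic,
documented convention; the choice within a tie is immaterial by
construction). The cluster count is the effective number of features.

PCA runs on the representatives after median imputation of missing values
(used strictly for deriving components, never exported) and
z-transformation. Component signs are fixed so each component's
largest-magnitude loading is positive, making scores byte-reproducible.
Retained-component estimates:

- *acceleration factor*: with eigenvalues e₁ ≥ e₂ ≥ …, the acceleration at
  interior position i is aᵢ = eᵢ₊₁ − 2eᵢ + eᵢ₋₁; the retained count is
  argmaxᵢ aᵢ − 1, floored at 2 (ties to the smallest i);
- *parallel analysis*: 100 seeded standard-normal matrices of the same
  shape, standardized; the retained count is the number of observed
  eigenvalues above the per-rank 95th percentile of the null (the
  percentile convention is a documented choice).

Sample outliers are flagged on *any* of the top-n components (n from the
acceleration factor) at more than the configured number of SDs from the
component mean — the conservative QC reading, since a sample extreme on
one informative axis is suspect regardless of the others. Optionally,
extreme cells can first be converted to missing (then imputed) or
winsorized to the most extreme non-flagged value on the same side of the
median; this affects only the PCA working copy, never the exported data.

## Filtering pipeline

Six ordered steps, each logged with threshold, removed identifiers and
before/after counts: (1) samples at ≥ 80% missingness; (2) features at
≥ 80% missingness, xenobiotics exempt; (3) samples at ≥ the user
threshold, recomputed; (4) features at ≥ the user threshold, xenobiotics
exempt; (5) samples with |TSA − mean| > t·SD using complete features only;
(6) PC outliers as above, recomputed on the survivors. Missingness
comparisons use ≥ (a threshold of exactly 20% removes a 20%-missing
entity), abundance-profile comparisons use strict >. User missingness
thresholds of 0 disable steps 3–4 (no-exclusion setting). An empty matrix
after any step raises an error naming the step. Strict idempotence of the
whole pipeline is not guaranteed — the TSA and PC means/SDs are recomputed
on the reduced data — but holds on data without borderline samples.

## Batch effects and power

η² = SS_between/SS_total from one-way ANOVA per categorical batch
variable, for sample missingness and TSA. All variables together enter an
additive linear model on dummy encodings with type-II sums of squares
(SS_term = RSS without the term − RSS of the full model); a term whose
columns add no rank to the design is flagged aliased rather than silently
absorbed. "Multi-term" here means several batch predictors for one outcome
at a time; a joint multivariate-response model is out of scope. Continuous
metadata columns are rejected with a message rather than binned.

Power: two-sided two-sample t-test via the noncentral t with
ncp = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2 (the far-tail term is clamped where
the noncentral CDF underflows); linear-model F-test via the noncentral F
with ncp = f²·n, df₁ = k, df₂ = n−k−1. Curves are evaluated on fixed
effect-size grids (d ∈ {0.1, …, 1.0}; f² ∈ {0.005, 0.01, 0.02, 0.05, 0.1,
0.2}) at effective sample sizes n·(1−q) for q at the quartiles of the
observed feature missingness, quantifying the power cost of missing data.

## Synthetic data

`metaboqc.simulate.generate_fixture` produces seeded datasets with known
truth; the defaults (200 samples × 60 features, 3 correlation blocks with
latent within-block correlation 0.9, 2 batches with ±15% multiplicative
median shifts, 5% overall cell missingness on the core features, 10
planted extreme cells, 1 whole-profile ×10 outlier sample, 1 PC-outlier
sample, 4 presence/absence xenobiotics at ~85% missingness, 4 derived
ratios) are the conditions under which the test suite exercises the
pipeline. Design notes:

- Abundances are exponentiated correlated Gaussians (log-scale SD drawn
  from 0.2–0.45), giving the right-skewed marginals typical of curated
  metabolomics panels while keeping single-feature tails mild enough that
  a 5 SD profile threshold separates planted outliers from the bulk.
- Half of the core features are fully observed and the rest carry
  Bernoulli missingness at twice the requested overall rate, so the
  overall rate matches the request while complete features — required by
  the TSA-complete metric — exist, as they do in real panels.
- The PC-outlier sample is shifted by +10 feature-SDs on a few complete
  features of one block (including that block's representative). A
  negative shift is impossible on a non-negative abundance scale; the
  one-sided TSA displacement of this pattern is ~2 SD, far below the 5 SD
  TSA threshold, so the sample genuinely reaches the PCA step.
- Derived features are ratios of a complete and an incomplete parent, so
  parent missingness propagates into them.
- Xenobiotics are present in ~15% of samples, testing the exemption rules
  at realistic severity.

What passing these tests shows: the statistics equal independent
brute-force implementations; planted structure of known geometry is
recovered; the exclusion bookkeeping is exact; outputs are deterministic.
What they do not show: behavior under missing-not-at-random mechanisms
tied to abundance, instrument drift within batch, heavy-tailed
contamination, or sample sizes below ~20 — the generator does not emulate
these, and real-data thresholds should be chosen by inspecting the report,
not inherited from the defaults. Test and acceptance problem sizes
(200 × 60 default, 20 replicate seeds for structure recovery, 10,000-rep
Monte-Carlo power validation) are the package's chosen verification scale.

## Numerical conventions

Quantiles interpolate linearly between order statistics. z-transforms use
the n−1 SD. Floats are written with 12 significant digits; reruns with
identical inputs and seed are byte-identical, including report-embedded
figures (no timestamps are written anywhere). All randomness (Shapiro
subsampling, parallel analysis, the cosmetic k-means coloring in the
report) derives from the configured `rng_seed`.
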