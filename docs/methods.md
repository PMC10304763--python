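# Methods

`cfmeth` implements the computational core of a cell-free DNA (ccfDNA)
methylation study: estimating which cell types released the DNA found in
plasma, and finding methylated regions whose levels stratify patients —
here modelled on acute coronary syndrome (ACS) with its three clinical
types (unstable angina, NSTEMI, STEMI) against healthy controls.  Real
cohorts of this kind are controlled-access, so the package ships
generators that emulate their statistical structure with known ground
truth, and every claim the test suite makes is a claim about recovery of
that truth.

## Signature construction

The deconvolution reference is a methylation atlas: a probe × cell-type
matrix of beta values (methylated read fraction per CpG) from purified
cell and tissue types.  Atlases are merged on probe ID (inner join by
default, because downstream selection needs complete rows), rows with
missing values or population variance `< 0.001` on the beta scale are
dropped, and replicate columns are pooled by arithmetic mean.  The
variance threshold interprets "variance below 0.1%" on the beta scale,
where 0.001 is the magnitude that separates flat rows from informative
ones; it is configurable.

Cell-type-specific CpGs are then selected four ways:

* **Top scaled (hyper/hypo).**  Each row is divided by its sum; for each
  cell type, in deterministic (sorted) column order, the `k_top = 100`
  probes with the highest scaled value in that column are taken.  A probe
  claimed by any earlier cell type is skipped (a single exclusion list is
  shared across cell types *and* both directions, which makes all top-k
  sets pairwise disjoint).  The hypomethylated pass repeats this on
  `1 − beta`, reversed **before** row scaling.  Ties break on probe ID.
  Row scaling makes the selection invariant to multiplying a row by a
  positive constant, which the tests assert.
* **Most differential (one vs rest).**  On the unscaled matrix: with ≥ 2
  replicate columns on both sides, probes are ranked by ascending one-way
  ANOVA p-value; on a pooled atlas by
  `|beta_target − mean(others)| / (sd(others) + 1e-6)` with the population
  standard deviation.  `k_diff = 200` per cell type by default.
* **Neighbours.**  All atlas CpGs within 50 bp (same chromosome) of a
  selected CpG.
* **Pairwise-specific.**  For every unordered cell-type pair, the
  `k_pair = 1` not-yet-selected probe maximising `|beta_A − beta_B|`.
  This per-pair max-difference rule is this package's declared procedure;
  `k_pair` is configurable.

Each probe records the first selection route that claimed it
(hyper > hypo > differential > neighbor > pairwise), and identical inputs
produce byte-identical signature files.

## Deconvolution

Given a signature `S` (CpGs × cell types) and a bulk beta vector `b`
(intersected on probe ID, missing values dropped pairwise, at least
`max(10, n_cell_types)` shared probes required), proportions `x` solve
`S x ≈ b` under one of four models, none with an intercept (proportions
have no baseline term):

* `nnls` — Lawson–Hanson non-negative least squares;
* `qp` — the quadratic program `min ‖Sx − b‖²` s.t. `x ≥ 0`, `Σx = 1`
  (SLSQP from the normalised NNLS start; feasibility is asserted to
  1e-8);
* `svr` — linear support vector regression without intercept and with
  `ε = 0` (an ε-tube of 0.1 on a beta-scale response ignores most of the
  signal and recovers mixtures no better than 0.1–0.15; with `ε = 0`,
  `C = 1`, noiseless recovery is exact to ~1e-5);
* `rlm` — Huber M-estimation robust regression.

Negative coefficients are truncated at zero and the vector renormalised
to sum to one (already satisfied for `qp`), so the output is always a
probability vector over cell types.

`nnls` and `qp` minimise the same objective and differ only in where the
sum-to-one normalisation enters; on noisy benchmarks their RMSEs coincide
to ~0.2% with either marginally ahead depending on the draw.  Model
ranking therefore treats them as one solver family (equivalence band 1%
relative); the substantive ranking claim — constrained least squares
beats robust regression beats SVR on simulated mixtures — is asserted
against `rlm` and `svr` directly.

## Mixture benchmarking

`simulate_cell_mix` draws proportions from a flat Dirichlet (the least
informative simplex prior; configurable by passing explicit proportions),
forms `atlas · p`, adds Gaussian noise on the beta scale and clips to
[0, 1].  RMSE pools over every (sample, cell type) entry.  The additive
Gaussian model isolates solver behaviour; binomial read sampling — the
realistic noise for bisulfite counts — lives in the cohort generator
instead, deliberately in a different module.

## From genomic calls to probes

Bisulfite callers report both strands of the symmetric CpG dyad; a
minus-strand call at position *p* is summed into the plus-strand call at
*p − 1* (orphan minus calls are moved there with a warning), conserving
total counts.  Collapsed calls are matched to an array-style probe
manifest by exact (chromosome, position); several records matching one
probe are combined by the coverage-weighted mean
`Σ methylated / Σ coverage`.  Internally all coordinates are 1-based
closed; Bismark coverage files are read as 1-based and
bedGraph/MethylDackel files as 0-based half-open, converted at the reader
boundary.  Minimum coverage defaults to 1.

## Differential methylation

The genome is partitioned into 500 bp windows anchored at position 1 of
each chromosome (step = width, so the tiling is a partition and needs a
fixed anchor for reproducibility).  Windows keep per-sample summed counts
and require `min_cpgs_per_window = 3` covered CpGs in every sample — a
guard against single-CpG windows.

Per window, differential methylation between condition and control is a
binomial logistic regression of per-sample (methylated, total) counts on
the group indicator.  With a single binary covariate the ML estimate is
the pooled proportion per group, so the 1-df likelihood-ratio chi-square
is computed in closed form, vectorised over all windows — no iteration,
no convergence failures.  The test agrees with Fisher's exact test on the
pooled 2×2 table within an order of magnitude, and under a binomial null
(coverage Poisson(10)+1, 10 vs 10 samples) its empirical type-I error at
α = 0.05 falls in [0.03, 0.07].  No overdispersion correction is applied.
The methylation difference is the coverage-weighted pooled difference in
percentage points.

Multiple testing uses Benjamini–Hochberg FDR by default — conservative
and transparent; a `slim-approx` option additionally scales BH by a
Storey-type null-proportion estimate (`pi0` from the p > 0.5 mass) for
users who want a q-value-style estimate, and the method slot accepts
further estimators.  DMRs require `q ≤ 0.01` **and** `|Δ| ≥ 25`
percentage points, with direction from the sign.

## Severity association

ACS types map to numeric severity UA = 1, NSTEMI = 2, STEMI = 3
(clinical ordering).  Whether healthy controls enter these regressions is
genuinely open; the default excludes them, and `include_controls` codes
them 0.  Per DMR, ordinary least squares fits

    Y ~ β0 + β1·DNAmeth + β2·ccfDNAlevel

with Y the severity code (or a clinical marker), methylation in percent
and the ccfDNA plasma concentration (ng/ml) as covariate — total ccfDNA
is elevated in disease regardless of tissue of origin, so the covariate
controls for amount rather than composition.  β1 is tested by t-test; the
reduced model drops only the methylation term, so the nested ANOVA
F-statistic equals t² identically (asserted to 1e-8 on every fit).
Severity is treated as a continuous response, as the linear-model
formulation implies; ordinal regression is out of scope.  DMRs with
`p(β1) ≤ 0.05` are retained.  On pure-null cohorts the retained fraction
is calibrated to [0.03, 0.07]; on generated cohorts with known β1 the
95% CI coverage over 100 replicates lies in [0.90, 0.99].

Clinical markers are modelled untransformed (no transformation is
standard for this screen).  Single-marker ACS-type classification uses an
unpenalised multinomial logistic fit with in-sample misclassification
rate (appropriate for one-predictor models on ~29 samples without a
holdout); complete separation falls back to an L2-penalised fit and is
flagged.

## Multivariate classification and PCA

ACS-type classifiers — random forest (500 trees), PLS-DA (PLS regression
on one-hot labels, class by argmax, components chosen by CV), and
penalized multinomial regression (L2, C over a 4-point grid by CV) — are
trained on a stratified 70/30 split.  Centering/scaling parameters are
learned on the training split only and applied to all evaluation data,
including external cohorts.  Cross-validation is stratified k-fold
repeated 10 times with k capped at the smallest training-class count
(plain 10-fold is infeasible when a class has fewer than 10 training
samples).  A label-permutation control trained the same way must perform
at chance (binomial test against the majority-class frequency).

PCA is centered, not scaled (prcomp-style default on methylation
percents), returning the first two components with explained-variance
fractions.

## Targeted-panel normalization

Targeted panels show location/scale bias against WGBS.  The pipeline:

1. `t = ln((x + 1) / ((100 − x) + 1))` — a pseudo-count log transform,
   finite on all of [0, 100];
2. quantile normalization of each validation sample onto the pooled
   discovery distribution (average ranks on ties, linear interpolation
   into the sorted target, so unequal lengths are supported; with an
   equal-length target the sorted output equals the target exactly);
3. ComBat: parametric empirical-Bayes location/scale batch adjustment
   without covariates, batch = cohort, applied jointly to all DMRs —
   feature-wise standardisation, per-batch location/scale estimates,
   moment-matched normal/inverse-gamma priors, iterated posterior
   updates.  The implementation matches R `sva::ComBat` to 1e-4 on shared
   input, which the test suite verifies by running R;
4. the analytic inverse `x = (101·e^t − 1)/(1 + e^t)`, clipped to
   [0, 100] (round trip exact to 1e-9).

Note on expectations: empirical-Bayes shrinkage means ComBat is *not* the
identity on identical batches (scale shrinkage moves extreme features by
up to ~0.3 at 10 samples/batch), and a raw-scale constant shift is only
removed per-feature when feature scales are homogeneous; what is always
removed is the overall batch offset and the between-batch variance
component, which is what the tests assert.

Concordance between cohorts is the Pearson correlation of per-DMR mean
differences (condition − control, percent), evaluated on the discovery
DMR windows, plus counts of DMRs replicating the q cutoff, the sign, and
the 25-point effect size.

## Synthetic data

`make_synthetic_atlas` plants, per cell type, disjoint blocks of hyper-
and hypomethylated marker CpGs (target at `0.5 ± contrast/2`, all other
cell types at the opposite level; contrast 1 gives one-hot markers)
against a Beta(5, 5) background, with probes every 100 bp on a synthetic
chromosome — five CpGs per 500 bp window, comfortably above the window
filter.  Default contrast 0.9 reflects that real purified-cell markers
are strong but not binary.

`simulate_wgbs_cohort` mirrors a small four-arm study: 8 controls,
8 STEMI, 7 NSTEMI, 6 UA.  Each group mixes the atlas cell types with a
healthy baseline whose first (granulocyte-like) component rises by
0.05 per severity unit — granulocytes dominate plasma ccfDNA and increase
in disease.  Per sample, planted DMR windows shift beta by ±40 pp in the
target group (alternating sign), severity-linked windows by
`slope · severity`, then coverage is Poisson(10)+1 per CpG and methylated
reads Binomial(coverage, beta).  ccfDNA concentrations are drawn per
group (means 8 / 18 / 22 / 26 ng/ml, disease elevated, matching the
few-to-tens range of plasma), and simple troponin-, CK-, LVEF- and
CRP-like markers trend with severity.  `simulate_targeted_panel`
restricts to a CpG panel, distorts the transformed scale by
`t → scale·t + shift`, and resamples reads at panel coverage.

What the generator does **not** emulate: sequencing error and conversion
artifacts, fragment-length structure, correlated CpGs within a region
beyond shared window shifts, cell-type proportions varying within a
group, and marker CpGs interacting with planted shifts other than by
clipping.  Passing tests therefore demonstrate correct recovery under the
stated statistical model, not performance on real cohorts.

## Determinism and problem sizes

All randomness flows from explicit seeds; workflows derive per-stage
substreams from one global seed (multiplicative hash + CRC of the stage
name, kept below 2³¹).  The reference evaluation uses desk-scale sizes —
50 noiseless and 200 noisy mixtures, 2000 null windows, a 510-window
cohort for planted-DMR recovery, 100 severity replicates, and a
5000-CpG / 29-sample end-to-end study — chosen so the whole evaluation
runs in about a minute on one CPU while keeping every calibration
interval at ±4 standard errors or wider.

## Known limitations

* SLIM q-values are approximated (BH, optionally pi0-scaled); exact SLIM
  internals are not reimplemented.
* Probe matching is exact-position only; region-overlap ("multiple
  mapper") modes are not implemented.
* The severity model is linear in a continuous severity code; ordinal or
  rank-based alternatives are not provided.
* Misclassification rates for single-marker models are in-sample by
  design and optimistic by construction.
* Sliding windows with step < width are not supported (the tiling is a
  partition).
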