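# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `psblup`.

## Mixed models and REML

Every model in the package is a Gaussian linear mixed model

    y = X beta + sum_t Z_t u_t + eps,   u_t ~ N(0, sigma2_t K_t),
    eps ~ N(0, sigma2_e I)

where each random term is either a categorical factor (`K_t = I`) or a
clone-level relationship kernel. Variance components are estimated by
REML. The residual variance is profiled out analytically, leaving the
variance ratios `gamma_t = sigma2_t / sigma2_e` as free parameters on a
log scale bounded in `[e^-25, e^12]`; the lower bound operationalises the
zero boundary, and ratios below 1e-8 are reported as exactly 0.

Three computational routes evaluate the same profiled criterion:

* **eigen** — one random term: `Z K Z'` is diagonalised once and the single
  ratio is optimised by bounded golden-section/parabolic search
  (`xatol` 1e-12). This is the route the cross-validation loops use.
* **dense** — small row counts (≤ ~700): `H = I + sum gamma_t Z_t K_t Z_t'`
  is built and Cholesky-factorised per evaluation.
* **sparse** — plot-level trial models: Henderson's mixed-model equations
  are assembled sparsely and factorised with SuperLU under the symmetric
  `MMD_AT_PLUS_A` ordering; the identity
  `log|H| + log|X'H^-1 X| = sum_t q_t log gamma_t + log|M|` converts the
  factorisation into the REML criterion.

Multi-ratio optimisation uses L-BFGS-B with numerical gradients
(step 1e-5); with a single ratio the exact bounded 1-D search is used on
whichever objective applies. This design was chosen over EM or
average-information updates because it needs an order of magnitude fewer
factorisations at these problem sizes and behaves robustly when components
sit on the zero boundary. The test suite verifies the routes against
closed-form balanced-ANOVA REML, against a brute-force likelihood grid,
and against each other (agreement to 1e-6).

The reported restricted log-likelihood includes `+0.5 log|X'X|`, making it
invariant to the fixed-effect parameterisation; likelihood *differences*
between nested models are unaffected.

A fit that does not converge is returned flagged, not raised; downstream
cross-validation records a missing prediction for that fold, which is what
the quality filter counts.

### Likelihood-ratio test for the column variance

Whether the random column effect enters a trial model is decided by a
restricted LRT on `sigma2_c`. The test statistic `2(logRL_full −
logRL_reduced)` is truncated at 0; its null distribution is obtained by
parametric bootstrap from the reduced fit (default 1000 draws), with a
50:50 chi2(0)/chi2(1) mixture available as a cheap approximation. The
pipeline's automatic column decision uses the mixture by default and the
bootstrap on request — the mixture is slightly conservative for small
level counts but three orders of magnitude cheaper.

## Trial models

* **Trial adjustment.** In environments split into early/late maturity
  trials, the trial contrast is estimated from the check plots only, with
  the trial fixed and check, block, row, column random; the estimated
  contrast is subtracted from every plot of that trial, for all traits
  regardless of significance.
* **Entry means.** The clone enters in cell-means coding (no intercept),
  so the BLUEs are the AEMs directly and their covariance matrix feeds the
  heritability. Scopes: single environment (block/row/column random),
  across environments (environment, clone × environment, and the spatial
  factors nested in environment), and across-all-but-one (for predictions
  whose spectra come from the excluded environment).
* **Outliers.** Plots with |studentized residual| > 4 (configurable) are
  dropped once and the model refitted — a deterministic replacement for
  manual residual-plot inspection; at the default threshold essentially no
  Gaussian data are removed.
* **Heritability.** `H2 = sigma2_g / (sigma2_g + vbar/2)` with `vbar` the
  exact mean over clone pairs of `Var(AEM_i − AEM_j)` — not the
  2×mean-variance shortcut. `sigma2_g` comes from a refit with the clone
  random. On a plot basis, `H2 = sigma2_g / (sum of all components)`;
  whether interaction variances belong in that denominator is a modelling
  choice, recorded here, not a claim about any external convention.
* **Channel heritabilities** are computed per channel × flight date with
  the across-environment model, or per channel across dates by adding the
  flight date and all its interactions (clone×date, date×environment,
  clone×date×environment, block/row/column×date) as random terms.

## Kernels

* `G = ZZ'/m` with markers centered by mean dosage by default (the raw
  cross-product is available behind a flag; both are tested). The
  denominator is the marker count, not a heterozygosity sum; a
  VanRaden-style normalisation can be layered on by the caller.
* Dominance uses the digenic covariate `w = d(4−d)/6` — the fraction of
  heterozygous pairs among the C(4,2) = 6 allele pairings of a tetraploid
  — column-centered, with the cross-product rescaled to mean diagonal 1.
* Epistatic kernels are Hadamard products `G∘G, G∘D, D∘D`, each rescaled
  to mean diagonal 1 so variance components stay comparable in the
  five-kernel model.
* `M = SS'/m_s` from clone-level channel × flight-date entry means, scaled
  and centered per column. Two-environment combinations: `cjM`
  column-joins the two matrices (equivalently, averages the two kernels —
  an identity the tests verify), `MAEM` takes per-clone entry means across
  environments per channel (the pipeline uses the plot-level across-
  environment model; the clone-level helper averages the per-environment
  entry means).
* `C = x·M + (1−x)·G` for `x` in [0, 1]; convexity preserves positive
  semidefiniteness, and the endpoints reproduce the pure models bit for
  bit under a shared cross-validation seed.

All emitted kernels are checked symmetric to 1e-10 and PSD to a relative
eigenvalue tolerance of 1e-8.

## Prediction

Kernel BLUP fits intercept + one random genetic term per kernel on the
training clones (eigen route for one kernel, dense for several).
Validation clones are predicted by the conditional-expectation formula
`mu + sum_t sigma2_t K_vt (sum_t sigma2_t K_tt + sigma2_e I)^-1 (y − mu)`;
an equivalent masked mixed-model-equation route exists and the two are
held to 1e-8 agreement on small instances by the tests. Cross-validation
partitions clones uniformly (fold sizes differ by ≤ 1, every clone
validated exactly once per replicate, deterministic in the seed, no family
stratification), yielding `n_folds × n_reps` PA values; the quality filter
flags (never deletes) results with |CV| > 150% or more than 100 missing
predictions, computing the CV over non-missing PAs. PA is summarised per
fold and reported as the median; checks participate like any clone once
they have entry means.

The weight grid search (default x = 0, 0.05, …, 1) shares fold assignments
across all weights, so the x = 0 and x = 1 rows are exact replicas of the
pure-G and pure-M runs. Flight-date subset analysis rebuilds `M` from the
selected dates' columns only, again with common folds.

## The synthetic-data generator

The generator emulates the study design the pipeline assumes; its defaults
are the study conditions: 458 test clones in 107 full-sib families plus 8
check cultivars replicated once per block, 5 environments (8 blocks each,
≤ 6 columns per block), the two most recent environments split into an
early (3-block) and a late (5-block) maturity trial with families assigned
alternately, and spectra in two environments on 3 flight dates with 5
shared channels (one of them missing in the second year) plus one
year-specific channel per year — 7 distinct channels, hence 21
channel-date features per environment after imputation.

* **Genetics.** Founder dosages are Binomial(4, p) with marker frequencies
  p ~ U(0.1, 0.9); gametes assume bivalent pairing without double
  reduction (hypergeometric: 2 of the parent's 4 alleles), so offspring
  dosage is the sum of two gametes and expected offspring dosage is the
  mid-parent mean. Markers are unlinked; there is no recombination map.
  The default 1000 markers are far fewer than a real array leaves after QC
  but are statistically ample for kernels over a few hundred clones.
* **Traits.** Genetic values are additive (i.i.d. normal effects on
  centered dosages) plus dominance generated from the same digenic
  covariate the D kernel uses — so G + D is the true model whenever the
  dominance fraction is positive. Plot values add trial, environment,
  clone × environment, block/row/column (i.i.d., exchangeable — no spatial
  autocorrelation), and residual effects. Variances are solved so the
  entry-mean heritability matches the configured target:
  `sigma2_ge + sigma2_e = E (1 − h2)/h2` with `sigma2_g = 1`; spatial
  variances are 10% of the residual each. With 5 environments this
  recovers targets 0.3/0.7/0.9 within the tests' ±0.1 band at 300 clones;
  at ≲100 clones the low-heritability case frequently hits the REML zero
  boundary — a property of the design, not of the estimator.
* **Spectra.** Each channel-date reflectance loads on a clone-level latent
  genetic score, shared across dates with coherence 0.15 and correlated
  with the traits' genetic values through their spectral-overlap
  fractions; clone × environment, spatial, and residual effects split the
  non-genetic variance 30/15/55. The defaults (plot-level channel
  heritability 0.25) were derived from these variance-bookkeeping formulas
  to give per-date entry-mean heritabilities near 0.4 and across-date
  values near 0.2 — the across-date estimates sit well below per-date ones
  because most spectral genetic signal is date-specific.
* **Determinism.** All draws flow from `SimConfig.seed` through named
  child streams (CRC-derived), so outputs are bit-identical for a given
  config and individually stable per stage.

What the generator does *not* emulate: real reflectance distributions
(values are Gaussian around channel intercepts, not physical
reflectances), spatial autocorrelation within fields, genotype-calling
error structure, linkage, or selection history in the founders. Passing
tests therefore demonstrate the statistical machinery — estimator
correctness, calibration, bookkeeping — not field-level realism.

## Preprocessing

Marker QC removes markers with ≥ 20% missing calls, then markers with
minor allele frequency (mean dosage / 4) below 5%, then median-imputes the
rest; the filter order matters and is fixed (MAF on post-missingness
data). Medians of an even count can be half-integer and are kept as
computed. Spectral preprocessing per environment: per-column z-scaling
(sample SD, ddof 1), PCA outlier flagging of whole plot-spectrum rows
(score > 4 SD on any component among those explaining 90% of variance —
whole rows because a bad flight frame corrupts all channels of a plot),
median imputation of the flagged cells. The per-environment blocks are
then stacked and channel-date columns entirely missing in one year are
filled by predictive mean matching: least-squares regression on the
complete shared channels, each missing cell copying the observed value of
one of the 5 nearest-prediction donors (uniformly at random, seeded) — so
imputed values always occur among observed donors. Observed cells are
never modified by any imputation step.

## Numerical choices and edge cases

* Variance ratios at the boundary are pinned via the log-scale bounds; the
  MME diagonal uses 1/gamma, which stays finite at the bound.
* Kernel factors for simulation/BLUP-recovery use a symmetric PSD square
  root (eigendecomposition with negative eigenvalues clipped), so
  rank-deficient kernels (duplicated clones, zero dominance) are handled
  without jitter; a diagonal jitter is applied only if a solve reports
  non-PSD within tolerance.
* Rank-deficient fixed designs raise an error naming the aliased columns
  (pivoted QR).
* Missing responses are listwise-deleted with their design rows.
* The quality filter treats an exactly-zero mean PA (undefined CV) as
  failing the CV clause, with the reason recorded.

## Problem sizes used in the checks

The test suite and the acceptance script run the study at reduced scale,
chosen once as the package's standard desk-scale conditions: 300 clones ×
75 families for heritability recovery (8 seeds per target in the tests, 5
in the script), 96 clones for the full-pipeline scenario runs, 64 clones ×
20 (null) / 10 (weight-search) seeds for the Monte-Carlo calibrations with
cross-validation at 3–5 replicates, and full 5 × 25 cross-validation
wherever a single run suffices. The calibration Monte-Carlos use a raw
clone-level spectral matrix (plot values per clone, scaled) rather than
the model-based channel entry means; the model-based route is exercised by
the pipeline and its integration tests.

## Known limitations

* No AR1 or other spatial-correlation structures; spatial adjustment is
  purely through the design factors.
* No heterogeneous residual variances per trial or environment.
* Single-trait models only; no multi-trait or Bayesian (BayesB-style)
  alternatives.
* The exact bootstrap LRT is expensive; the pipeline's default column
  decision uses the chi-bar-square approximation.
* Per-cell (rather than per-row) spectral outlier flagging is not
  implemented.
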