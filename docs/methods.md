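# Methods

## Scope and model

`groupscreen` screens high-dimensional omics features for association
with a continuous outcome — the motivating application is the log of
mean fasting blood triglyceride regressed on array methylation and SNP
genotypes — using penalized joint regression rather than locus-by-locus
tests. The estimator is the elastic-net group LASSO

    min_beta  (1/2n) ||y − X·beta||²₂
              + λ₁ Σ_j w_j ||beta_j||₂
              + (λ₂/2) ||beta_pen||²₂ ,

where the coefficient vector is partitioned into n_g groups beta_j of
size d_j. The unsquared two-norm penalty zeroes entire groups at once,
which is what makes grouped codings (indicator-coded SNPs, interaction
blocks) selectable as units. A small ridge term λ₂ stabilizes the
optimum when predictors are correlated or duplicated across overlapped
groups.

Because the model is fitted jointly over all loci, residual genetic
correlation between related individuals is much smaller than in
single-locus regressions; family structure is deliberately not modeled
(and household effects are out of scope).

## Design construction

* **Methylation** enters as M-values, `logit(beta)` with beta clipped
  to `[eps, 1−eps]`, `eps = 1e-6` (array data contain exact 0/1 beta
  values; the clip keeps the transform finite and monotone).
* **Genotypes** are first oriented so the counted allele is the minor
  allele in the analyzed sample, with missing calls imputed to the
  per-SNP mode. Two codings are available: the *general* (categorical)
  coding with indicators `1{g=1}, 1{g=2}` forming a size-2 group, and
  the *linear allele effect* (LAE) coding, a single allele-count
  column. The identity `count = I₁ + 2·I₂` holds exactly and is
  property-tested.
* **Covariates** — intercept, age, smoking, and principal-component
  scores (4 methylation PCs and/or 4 genotype PCs depending on the
  workflow) — form a single unpenalized group, solved by exact least
  squares within each sweep. PC scores are computed on the
  column-centered M-value (resp. allele-count) matrix with a
  deterministic sign convention. The outcome is centered.
* **Interactions.** For every CpG–SNP pair on the same chromosome whose
  positions differ by strictly less than `fraction × chromosome length`
  (default fraction 1e-4, roughly a 10 kb window on a full-length
  chromosome; chromosome length defaults to the maximum observed
  position), a size-5 strong-hierarchy group
  `[M, I₁, I₂, M·I₁, M·I₂]` is appended with fresh copies of the
  main-effect columns. Overlap therefore exists only at the
  source-feature level; a `duplication_map` records, for every design
  column, the feature(s) it represents, and a feature's total effect is
  recovered by summing its copies' coefficients (rescaled back to the
  original column units).
* **Standardization.** Penalized columns are scaled to zero mean and
  unit population standard deviation (constant columns are left
  unscaled and can never be selected); product columns are formed from
  the M-value copy and the raw indicators and then standardized
  themselves. Unpenalized covariates are left on their natural scale.
* **Group weights.** Penalized groups carry w_j = √d_j, the usual
  degrees-of-freedom correction, since the designs mix groups of sizes
  1, 2 and 5; a flag disables it. Coordinates are 1-based inclusive.

## Solver

Block-coordinate descent with majorize–minimize proximal updates: for
group j the quadratic term is majorized with the per-group Lipschitz
constant L_j = λmax(X_jᵀX_j)/n + λ₂ (largest Gram eigenvalue by power
iteration, exact for orthonormal and singleton blocks), and the block
moves to

    beta_j ← prox( beta_j(1 − λ₂/L_j) + X_jᵀ r /(n L_j),  λ₁ w_j / L_j ),

where prox is the group soft-threshold `z ↦ (1 − t/||z||)₊ z`. This
yields exact zeros (group active ⟺ block norm > 0, no epsilon), and the
objective is non-increasing at every sweep. Sweeps cycle in fixed
ascending group order for reproducibility, alternating one full sweep
with sweeps restricted to the currently active groups; convergence
(relative objective decrease below `tol` over a *full* sweep) is only
declared after a full sweep, so inactive groups are always rechecked. A
final stationarity (KKT) residual is reported, and `fit` tightens the
sweep tolerance when the objective plateaus before the KKT target
`kkt_tol` (default 1e-6) is met.

Defaults: `tol = 1e-8`, `max_sweeps = 2000`, ridge λ₂ = 1e-3·λ₁ ("a
slight ridge"; exposed as `lambda2` / `lambda2_ratio`). The pipeline
stages (cross-validation and the subsample fits of stability selection)
use `tol = 1e-6` instead: those fits feed support detection only, and
on half-samples with n < p the tiny ridge leaves the problem so weakly
strongly-convex that descent can crawl below 1e-8 per sweep
indefinitely without changing the selected support.

λ₁ is chosen by K-fold cross-validation (default 5 folds, seeded
partition) of mean squared prediction error over a descending grid of
50 log-spaced values from λ_max (the smallest penalty zeroing all
groups, computed from the covariate-only residual) down to 1e-3·λ_max,
with warm starts along the grid; ties resolve to the larger penalty.

## Stability selection and error control

Complementary-pairs subsampling: each of B draws (default B = 50, i.e.
100 half-sample fits; the count is configurable because the source
analyses are ambiguous between "pairs" and "subsamples") splits the
samples into two disjoint halves of size ⌊n/2⌋. Each half-sample fit
multiplies every penalized group's weight by an independent
U[w_low, 1] draw (default w_low = 0.5, the randomized-LASSO
convention; per-group rather than per-column because the selectable
units are groups), at the λ₁ fixed from full-data cross-validation. A
group's selection frequency π̂_j is the fraction of the 2B halves that
selected it, and q̂ is the average number of groups selected per half.
Non-converging halves raise by default; a lenient mode records and
excludes them.

The expected number of falsely selected groups above a frequency
threshold τ is bounded by E[V] ≤ p·M(τ, q, p). Three branches are
implemented and the pointwise minimum taken:

* the basic complementary-pairs bound q²/(p²(2τ−1)) for τ > 1/2;
* the r-concave worst-case tail of the per-pair simultaneous-selection
  count (mean (q/p)², grid 1/B) at threshold 2τ−1, r = −1/2;
* the r-concave worst-case tail of the selection frequency itself
  (mean q/p, grid 1/(2B)) at threshold τ, r = −1/4, which extends the
  control below τ = 1/2.

The r-concave worst case is computed exactly: the extremal pmf has
f^r linear on a truncated support {0..k}, so for each k the single
shape parameter is solved from the mean constraint by bracketed
root-finding and the maximum tail over k is returned (the computation
is validated in the test suite against a brute-force constrained
optimizer over all r-concave pmfs). Each bound is returned with the
branch that attained it. Threshold calibration (`tau_for_pfer`)
bisects over the attainable frequency grid {1/(2B), …, 1} — the bound
is a step function of τ constant between grid points, so finer
resolution is illusory — and returns the smallest grid τ whose bound
meets the target; an unreachable target raises. Selection applies the
strict rule π̂ > τ. When a workflow's calibration target is unreachable
even at τ = 1 (which happens when q̂/p is large, as in small synthetic
designs where cross-validation retains many groups), the pipeline
falls back to τ = 1 and selects nothing rather than fake control.

## Synthetic cohorts

The generator emulates the structure of a lipid-methylation cohort
with known sparse ground truth:

* genotypes i.i.d. Hardy–Weinberg per SNP, MAF uniform on (0.05, 0.5];
* methylation logit-normal: per-CpG mean uniform on (−2.5, 2.5), plus
  `latent_rank` (default 4) shared Gaussian factors with N(0, 0.5²)
  loadings and N(0, 0.8²) site-level noise on the logit scale — the
  latent factors are what make PC adjustment meaningful, and the
  logit-normal marginal makes the M-value transform exactly
  linearizing, giving clean recovery oracles;
* positions uniform without replacement on one chromosome, so the
  colocation filter has pairs both inside and outside its window;
* outcome: intercept (4.0) + Σ CpG effects·M + Σ SNP per-level effects
  + Σ interaction effects·(M × level indicator) + 0.02·age +
  0.3·smoking + N(0, noise_sd²), noise_sd default 1.0. Default effect
  sizes: |0.5| per causal M-value (alternating sign), (0.3, 0.6) per
  causal SNP level, (0.5, 1.0) per interaction level. Causal
  interactions are drawn among colocated pairs and their main effects
  are forced into the supports (strong hierarchy is enforced as an
  invariant). Age is U(20, 70), smoking Bernoulli(0.25), independent
  of the omics features.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (independent draws), kinship/household correlation, cell-type
composition or batch effects beyond generic latent factors,
probe-specific measurement error, and non-Gaussian outcome tails.
Passing recovery tests therefore demonstrate correctness of the
machinery under the generating model, not performance claims on real
cohorts.

## Problem sizes used in the checked experiments

The test suite exercises the workflows at desk scale: EWAS recovery at
n = 500 with 2,000 CpGs (3 causal) over 10 seeds; error control at
n = 400 with 1,000 CpG groups (5 causal) over 20 replicates; the
interaction screen at n = 500 with 500 CpGs × 500 SNPs and a
colocation fraction of 0.004, yielding roughly 2,000 size-5 groups
(2 causal interactions), over 10 seeds — all with B = 50 pairs. These
sizes keep the full suite runnable on a single CPU in minutes while
leaving every stage (CV, 100 subsample fits, calibration, reporting)
fully engaged.

## Numerical and design choices

* Proximal steps produce exact zeros; no active-set epsilon anywhere.
* Power iteration for block curvature runs to a 1e-13 relative
  fixed-point tolerance; orthonormal blocks give L_j = 1 exactly, so
  the closed-form one-sweep oracle holds to machine precision.
* Ties in cross-validation go to the stronger penalty; ties in report
  tables go to the smaller genomic position; sweep order is fixed.
* The Manhattan export plots −log(1 − π̂) (natural log, stated in the
  column name); π̂ = 1 is capped at −log(1/(4B)) to stay finite, a
  plotting artifact only. Interaction groups are placed at the floor
  midpoint of their CpG and SNP positions.
* The top-table's "marginally significant" flag for an interaction row
  reports whether the constituent CpG and/or SNP main-effect group
  itself exceeds the same calibrated τ used for selection.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning (cross-validation folds,
  subsample plan, per-half weight randomization); identical inputs and
  seeds reproduce results bit for bit.

## Known limitations

* The r-concave error bound assumes exchangeability and a
  better-than-random selection procedure; on synthetic data with
  correlated nulls (latent factors) the bound is conservative but not
  proof against model misspecification.
* With dense selection (q̂ a substantial fraction of p, typical for
  cross-validated penalties on small p) the E[V] target can be
  unreachable at any τ; the pipeline then reports τ = 1 and selects
  nothing. At epigenome scale (p in the hundreds of thousands,
  q̂ ≈ 100) calibration is informative.
* Single-chromosome interaction search only; no trans interactions, no
  LD-aware grouping, no positional smoothing of neighboring loci.
* The solver is single-threaded by design (reproducibility first); at
  the scales above this is not limiting.
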