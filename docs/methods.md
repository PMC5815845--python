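# Methods

## Generative model

The synthetic generator produces the data structure the pipeline assumes.
For m subjects and n voxels on a 3-D grid:

    X = μ + A·S + Σ_f B_f + E

- **S** (k_true × n): spatial sources. Each source's support is a sparse set
  of voxels (default 8% of the grid) grown as a few compact spherical
  patches (default 4) inside the task-active region — brain networks are a
  handful of contiguous foci, not scattered voxels. Loadings on the support
  are Laplace-distributed, then each row is z-scaled over all voxels.
  Laplace tails give the super-Gaussian marginals that make the sources
  identifiable by ICA; Gaussian sources would not be (and a test asserts
  exactly that failure mode).
- **A** (m × k_true): subject mixing scores, standard normal, columns
  z-scaled.
- **μ**: group-level task activation — `activation_effect` (default 0.5,
  Cohen's-d units against the per-voxel total SD) inside a central ellipsoid
  covering `active_fraction` (default 0.5) of the grid. Without it the
  planted model has zero group mean and the WMN mask would be empty; the
  mask stage only makes sense with a group effect to find.
- **B_f**: additive per-voxel batch offsets, one offset map per level of
  each batch factor (defaults mirror three factors with 3/2/2 levels and
  offset SD 0.3) — the structure the residualization stage must remove.
- **E**: i.i.d. Gaussian noise (default SD 0.5).

Behavioral variables are standard-normal latents with planted standardized
slopes on chosen component scores (`y = β·a_c + √(1−β²)·ε`, so the slope is
also the population correlation), then affinely mapped to realistic
marginals (d′ 2-back ≈ 2.5 ± 0.8, etc.; affine maps leave all correlations
intact). Defaults plant β = 0.24 from network 1 onto d′ 2-back and β = 0.25
from network 2 onto d′ 0-back — the magnitudes of the working-memory and
attention couplings the pipeline is meant to detect. FA columns (70 regions,
35 per hemisphere as `*_lh`/`*_rh`) are latents with a planted slope
(default 0.15 in three regions from network 1), mapped to FA scale
0.45 ± 0.05 and clipped to [0, 1]. Covariates (sex, age, handedness, Likert
scales, BMI, ICV) have realistic marginals and no planted effects.

The trial-level responder draws n-back responses from an equal-variance
signal-detection model: targets answered "target" with probability
Φ(d′/2 − c), nontargets with Φ(−d′/2 − c), each response missing with
probability `miss_rate`.

All generation is a pure function of (config, seed).

### What the generator does not emulate

No BOLD time series or hemodynamics, no first-level GLM, no spatial
autocorrelation beyond the compact supports and atlas blob smoothing, no
spatially structured noise, no lure-specific error processes. Passing tests
show the pipeline's statistics behave correctly under the linear-mixture
model it assumes — not that real scanner data satisfy that model.

## Pipeline conventions

**Task schedule.** 12 blocks of 14 stimuli (6 per condition), exactly 3
targets per block; 0-back targets are the letter "x"; 2-back targets repeat
the letter two back. 15 lures (letter matches one or three back without
being a target) are planted among the 84 2-back stimuli — a 17.9% lure
fraction. Blocks are built by constrained rejection sampling with exact
target/lure counts; infeasible requests raise after bounded retries.

**D-prime.** d′ = Φ⁻¹(H) − Φ⁻¹(F), hits and false alarms computed among
non-missing trials only. Extreme proportions are corrected as 0 → 0.5/N and
1 → (N−0.5)/N; with 18 targets and 66 nontargets a perfect responder scores
4.34, which is the ceiling the scoring must reproduce. The correction choice
is validated only through that ceiling; a log-linear correction would give a
different ceiling. Note an inherent small-sample property, not a bug: with
18 targets the inverse-normal transform is convex over the binomial spread,
so the mean recovered d′ for a planted d′ = 2 responder is ≈ 2.08.

**Exclusions.** Subjects are flagged for (a) missing responses in >30% of
all stimuli, (b)/(c) >30% of target/nontarget stimuli missing in ≥3 blocks
(with 3 targets per block, one missing target already trips a block), (d)
any cognitive measure beyond 4 SD of the pre-exclusion sample mean (computed
once, not iterated), (e) incomplete data. Flags are monotone in
missingness.

**WMN mask.** Subjects with missing-voxel counts above mean + 4 SD are
dropped, then every voxel with any remaining missing value. Per voxel a
one-sample t against zero (two-sided p, df = m−1); Benjamini–Hochberg FDR at
α = 0.05 (boundary inclusive); the mask is q ≤ α ∧ t > 0. The positive-t
restriction on a two-sided map, rather than a one-sided test, is a
convention; both differ only in the p-scale, and the one-sided variant can
be obtained by halving p before FDR.

**Batch residualization.** Each voxel's values are regressed on the batch
factor indicators; the standardized residuals (unit variance per voxel)
enter ICA and the association models. With no batch factors the matrix
passes through unchanged: per-voxel rescaling of a noise-free sparse mixture
divides each support voxel by ≈|s_v| (a soft sign), which would destroy
exact source recovery while removing nothing. With realistic noise the
distortion is mild; it is one reason recovered-vs-planted |r| sits near 0.8
in the full pipeline demo but above 0.99 for direct mixtures.

**Spatial ICA.** Voxels are observations, subjects variables: each
subject's map is centered and scaled, the data are PCA-whitened to k
dimensions, and a symmetric (parallel) fixed-point iteration with the
log-cosh contrast (α = 1) runs to convergence (max |diag| deviation < 1e-6,
max 1000 iterations, up to 5 seeded restarts on non-convergence; failures
are reported, never hidden). Sources are re-z-scaled; scores are the least
squares mixing coefficients, so `scores @ sources` reconstructs the
standardized data in the retained subspace. k is never chosen
automatically — the scree output informs the caller's choice, matching
practice. Because the direction of an IC is arbitrary, every component is
recoded so its largest-|loading| voxel loads positively (idempotent, leaves
the reconstruction unchanged). The implementation is cross-checked against
scikit-learn's FastICA in the tests (same sources to |r| > 0.999); keeping
the in-package loop makes the whitening orientation, convergence reporting
and restart policy explicit and keeps the external library available as an
independent oracle.

**Thresholding.** The annotation threshold is the (1−fraction) quantile of
|loadings| pooled over all k components (default fraction 0.10 — "the 10%
most extreme |z|"); association analyses always use unthresholded maps.

**Annotation.** Supra-threshold voxels are clustered by 26-connectivity
(configurable: 6/18/26), positive and negative loadings separately. Each
voxel is assigned to its maximum-probability atlas region if that
probability is ≥ 25%, ties toward the lower region index; regions
contributing > 10 voxels to a cluster are reported, with the percentage of
the region's labeled voxels covered and peak voxels per cluster and region.

**Associations.** All variables are z-transformed, so OLS coefficients are
standardized βs. Candidate predictors pass a collinearity filter that keeps
a variable only if it correlates ≤ 0.5 in absolute value with every
higher-priority variable already kept (priority = declared listing order).
Component models include the remaining components' scores as covariates;
voxelwise models do not. Variance explained is reported as the squared
partial correlation R² = t²/(t²+df) — a convention, chosen because the
quantity is available for every term from the t statistic alone.
BH-FDR runs over the declared family (predictors × components, or
predictors × voxels for the voxelwise maps). Underflowing p-values are
floored at 1e-300, never 0. Complete-case analysis throughout.

**Stability.** Per bootstrap run, two disjoint subject subsamples are drawn
and decomposed; each estimated component is matched to the best
|r|-correlated component of the full-sample reference (greedy per estimated
component by default — two estimates may share a reference; a one-to-one
assignment mode exists), sign-aligned, and the matched loadings of the two
halves correlated. Association models are refit per half and their βs
averaged after sign alignment (unaligned averaging would cancel).

**Cross-validation.** Per run the sample splits into training and test
subjects; the training decomposition is matched to the reference, its
sources projected onto the standardized test maps by least squares
(dual-regression-style; exact for correlated sources, unlike the S·x/n
shortcut which is only valid for orthonormal sources), and the projected
scores regressed on the performance measures with sex and age covariates.
The summary is the percent of runs with nominal p < 0.05 per
(component, measure). The permutation null shuffles the performance columns
across subjects; since projections do not depend on performance, the per-run
projected scores are computed once and reused across permutation repeats —
an exact reformulation asserted against the naive refit in the tests. The
empirical p uses the add-one estimator (1 + #{null ≥ observed})/(n_outer+1).
With a discrete, heavily tied statistic this estimator is valid but
conservative under the null (mean p well above 0.5); the tests assert
validity and conservatism rather than a uniformity that the tied case
cannot exhibit.

**FA associations.** Per region, the component's scores are regressed on
the region's FA with sex, age, handedness, ICV and the other components'
scores as covariates, fit through a Frisch–Waugh–Lovell residualization
that is exactly the full OLS (asserted against statsmodels). Hemisphere
scopes (both = lh/rh average, left, right) form a 3 × 35 FDR family. Two
global tests per component summarize the 70 region p-values: a two-sided
one-sample KS test against Uniform(0,1) (asymptotic by default; the exact
small-sample variant is available via `mode`), and a permutation test on
the count of nominally significant regions (scores shuffled, covariates
left attached; default 10000 permutations, reduced to 999 at desk scale).
The two tests respond to different alternatives: a broad graded association
across many regions moves the KS statistic (D ≈ planted-fraction for strong
effects), while a focal effect in a few regions can reach the permutation
count test yet leave KS unimpressive — visible in the demo, where three
planted regions at slope 0.15 sit near the detection edge at n = 300.

## Numerical and testing choices

- Whitened components carry unit variance across voxels (SVD-based,
  √(n−1) scaling); symmetric decorrelation uses the eigendecomposition of
  W·Wᵀ. Rank is checked before whitening; k beyond the numerical rank
  raises.
- Determinism: every stochastic operation takes a seed; decompositions and
  datasets are bit-reproducible under it. Derived seeds come from
  `SeedSequence` spawning and stay below 2³¹.
- Degenerate inputs (constant vectors/columns, empty masks, zero-variance
  source rows, empty p-vectors) raise typed errors rather than propagate
  NaNs; zero-variance voxels in t-maps are flagged with undefined p.
- Problem sizes in the test suite are chosen for single-CPU desk scale:
  recovery at m = 200 subjects × n = 2000 voxels, null calibration of the
  cross-validation at m = 300 × n = 20000 with 100 runs × 50 permutation
  repeats, FA calibration at n_perm = 999, Monte-Carlo checks at 50–200
  seeds. Statistical bounds in tests are derived from stated oracles
  (brute-force step-up FDR, recursive flood fill, closed-form OLS,
  bivariate-normal simulations) with 3-SE binomial slack; oracle code lives
  in the tests and never calls the implementation it checks.

## Known limitations

- Per-subject standardization inside ICA makes projected scores a
  subject-wise rescaling of the true mixing coefficients; correlations with
  behavior attenuate accordingly (the cross-validation detection rates in
  the demo, 48–80%, reflect this).
- The atlas generator produces isotropic Gaussian blobs spread by k-means —
  adequate for exercising the 25%-floor/argmax labeling logic, not a
  morphologically realistic parcellation.
- The KS test at 70 regions has limited power against focal FA effects;
  the permutation count test is the sharper instrument there.
- Greedy component matching can map two estimated components onto one
  reference component in low-SNR regimes; the one-to-one mode avoids this
  at the cost of forcing matches for unstable components.
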