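# Methods

This note records the statistical model the package implements, the design
choices that were genuinely open, the numerical conventions, and what the
synthetic cohorts do and do not establish about real data.

## The analysis model

The data are an `N × P` matrix `X` of per-subject voxel values on a skeleton
mask (for real data, FA values projected onto a thinned mean-FA skeleton and
masked at FA > 0.2) and a length-`N` behavioral score `y`. Scores are
analyzed one at a time; with a one-dimensional behavioral block the canonical
correlation problem has exactly one pair (K = 1) and degenerates to the
multiple correlation of `y` on the reduced imaging components. The package
exploits this: `fit_cca_single` solves an ordinary least-squares problem and
reports `R = √R²`, which is algebraically identical to the CCA solution and
numerically far better behaved than a generalized eigenproblem on a
rank-deficient block. The test suite keeps a dual route: the same quantity is
checked against an explicit normal-equations oracle and against an
independent CCA implementation.

Because `P ≫ N`, `X` is first column-centered and reduced by truncated SVD
to `Q ≤ N − 1` components. Centering statistics always come from the fitting
data and are reused for held-out projections.

### Choosing Q

`Q` is selected by leave-one-out cross-validation: for each candidate `q`
and each held-out subject, the SVD and the canonical fit are recomputed on
the remaining `N − 1` subjects, the fold solution's global sign is aligned to
the full-data solution (via the sign of the inner product of back-projected
voxel weights — fold components carry arbitrary signs), and the held-out
subject's centered feature row is projected to a held-out variate `u`,
paired with the held-out centered score `v`. The held-out pairs are pooled
across all `N` folds into a single Pearson correlation per `q` (a per-fold
correlation is undefined for single-subject folds). The selected `Q` is the
argmax, ties broken toward the smallest `q`.

A caveat the synthetic experiments make visible: when the signal is strongly
rank one, the CV curve rises at `q = 1` and then stays flat to within fold
noise (differences of order 0.003), so the argmax can land anywhere on the
plateau. The selection is still correct in the sense that matters — the CV
correlation at the selected `q` is at the plateau value — but the selected
integer itself is not stable, and summaries should report the curve, not
just the argmax.

### Permutation inference

Significance of the full-data `R` at the selected `Q` is assessed by
shuffling the entries of `y` (default 10000 permutations). Permuting `y`
leaves `X` — and therefore its SVD basis — unchanged, so each permutation
refits only the canonical pair on the same reduced scores; `Q` is selected
once on unpermuted data and held fixed, since re-selecting per permutation
would change the null hypothesis being tested. The implementation evaluates
all permutations in one matrix product using the identity
`R = ‖U_Qᵀ y_c‖ / ‖y_c‖` (the left singular vectors are orthonormal and a
permutation of a centered vector stays centered); equality with the
fit-by-OLS route is covered by tests. The p-value uses the add-one estimator
`(1 + #{R_null ≥ R}) / (1 + n_perm)`, which cannot be zero and is valid at
any `n_perm`.

### Bootstrap saliency

Reliability of each voxel's contribution is assessed by resampling subjects
with replacement (default B = 1000). Each fold's matrix is re-reduced by
SVD; fold components are rotated onto the full-data components by orthogonal
Procrustes (the full orthogonal group, because SVD components are defined
only up to sign — sign flips are exactly the reflections); the canonical
pair is refit on the aligned fold scores; the fold solution's global sign is
corrected against the full-data back-projected weights (the full-data
solution is the reference "fold": it is unique and deterministic); and the
fold weights are back-projected to voxel space. The bootstrap ratio is the
per-voxel mean over folds divided by the per-voxel standard deviation
(`N − 1` denominator). Voxels with `|ratio| ≥ 1.96` (the two-sided 5% normal
critical value) enter the signed saliency mask with the sign of their ratio.

Edge rules: a fold whose resampled score is constant is redrawn (at most 100
redraws in total, logged); a voxel whose weight distribution has zero
variance gets a `sign(mean)·∞` sentinel and a flag (all-zero distributions
get ratio 0); a fold whose matrix rank falls below `Q` is an error rather
than a redraw — with `Q ≤ N − 2` this does not occur in practice.

The saliency analyses in this repository run the bootstrap at `q = 5` even
though the CV-selected `Q` is often 1 for a rank-1 signal. The reason is a
resampling artifact worth knowing about: bootstrap duplication roughly
halves the effective sample size and inflates noise spikes, which can push
the signal direction out of a fold's *first* component even when it
dominates the full data. At `q = 1` the fold weights then jitter enough that
no voxel crosses 1.96 (while the |ratio| *ranking* still separates salient
voxels perfectly); a few components of margin make the fold subspaces
capture the signal in every fold. The ratio threshold itself is never
adapted.

### Covariate adjustment

Adjusted analyses residualize both blocks — every voxel column and the score
— on an intercept plus the named covariates (age in years, gender coded 0/1
through a configurable label map) before repeating the whole chain. Results
are reported as unadjusted and adjusted pairs. Rank-deficient covariate
designs are an error, not a silent drop.

## The synthetic cohorts

The generator plants a rank-1 latent association: a standard-normal latent
`z`, a unit-norm loading `a` supported on `n_salient` voxels with a
configurable fraction of negative signs, `X = s·z aᵀ + noise`, and
`y = α·z + β_age·age + β_gender·gender + ε`. The two scales are calibrated
so that the population correlation between the planted voxel-space variate
`X a` and `y` equals `rho` exactly:
`corr(Xa, y) = corr(Xa, z)·corr(z, y) = c_x · (rho / c_x) = rho`, with
`s = noise_sd·c_x/√(1 − c_x²)` and `α = r_y/√(1 − r_y²)`.

The split between the two legs is a real design choice. The voxel-side
alignment is held high (`c_x = max(0.98, √rho)`) because the planted spike
must exceed the spiked-covariance detection threshold
(`s²/noise_sd² > √(P/N)`) — with margin, so that it remains detectable
inside bootstrap folds where resampling halves the effective sample size. At
the default, the spike strength `c_x²/(1 − c_x²) ≈ 24` is about four times
the fold-level threshold at the largest simulated aspect ratios. A symmetric
`√rho` split would plant a direction that the leading SVD subspace provably
cannot find when `P ≫ N`; that regime does not correspond to real skeleton
data, whose strong anatomical covariance makes the leading components highly
stable and which yields full-data R in the 0.4–0.9 range at N between ~57
and ~163. `n_salient` does not enter the calibration because the loading is
unit-norm however many voxels carry it. At `rho = 0` only the score side is
zeroed: the loading structure remains in `X`, the score is independent of it
— the exact null.

Default conditions: N = 160 subjects (the upper, control-group end of the
emulated cohort sizes), ages uniform on [65, 80] years, gender
Bernoulli(0.5), unit noise, 50 salient voxels with 30% negative loadings,
confound coefficients zero (nonzero values inject age/gender effects into
the score only — sufficient to exercise the adjustment path). The skeleton
mask is a random arrangement of one-voxel-thick axis-aligned segments hitting
`round(skeleton_fraction · grid volume)` voxels exactly; the analysis is
geometry-agnostic, so only the mask bookkeeping, not anatomical shape, is
emulated.

What the generator deliberately omits: spatial autocorrelation between
voxels (the method makes no spatial assumption), non-Gaussian FA marginals
and their [0, 1] support, registration error, site effects, and any
multi-spike signal (the K = 1 analysis motivates a single planted
dimension). Passing the simulation suite therefore establishes correctness
of the algorithms and calibration of the inference under the stated model —
not robustness to the anatomical covariance structure of real skeletons.

## Numerical conventions

- Voxel columns follow the C-order raster scan of the mask (last axis
  fastest, `numpy.argwhere` order); column order is a pure function of the
  mask.
- Sign convention: `weight_y > 0` and `R ≥ 0`, so a positive back-projected
  voxel weight always means higher feature value ↔ higher score; map
  polarity is well-defined.
- Singular values below `1e-10·σ₁` are treated as zero everywhere: dropped
  from bases with a warning (never inverted), rejected as collinearity in
  the canonical fit, and rejected as rank deficiency in covariate designs.
- Variates are scaled to unit sample variance (ddof = 1).
- The display fill dilates each suprathreshold voxel's sign within a
  Chebyshev radius wherever mean FA > 0.2; voxels reached by both signs stay
  0, original suprathreshold voxels are never overwritten, and the result is
  marked display-only.
- All randomness flows through explicit integer seeds; identical config and
  seed reproduce summaries byte-for-byte.

## Problem sizes used in the shipped analyses

The simulation studies in `tests/` and `scripts/acceptance.py` use N = 50
cohorts with P = 200 voxels for null calibration (500 replicates, 199
permutations), N = 150 with P = 2000 for planted-signal recovery (20
replicates) and saliency (B = 300), and N = 160 with P ≈ 2000 for the
narrative analysis (10000 permutations, B = 1000). These sizes sit inside
the emulated study's range of N while keeping P at the low end; the
algorithms are dimension-agnostic, and the calibration analysis above is
what changes with P/N, not the code path.

## Known limitations

- Only one behavioral dimension per fit (K = 1); multi-pair deflation,
  sparse/regularized and kernel CCA variants are out of scope.
- No family-wise correction across scores is applied; scores are analyzed
  independently.
- The LOO-CV argmax is unstable on flat CV curves (see above).
- Confidence intervals for R are limited to the bootstrap SD of the fold
  correlations.
- The fill step is display-only and must not feed back into analysis.
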