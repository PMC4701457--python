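# Methods

## Problem setting

`patternreg` implements multivariate pattern regression for decoding a
continuous clinical score from per-subject 3D fMRI GLM coefficient maps
("beta maps").  The motivating design is a multi-site pediatric study in
which N = 57 youth performed a reward task in the scanner and were rated on
a 0–30 parent-report mania scale (PGBI-10M) at two time points: the study
screen years before imaging (mean 15.5, SD 6.3) and the assessment nearest
the scan (mean 4.7, SD 5.4, strongly right-skewed).  Roughly half the
sample (52.6%) was taking psychotropic medication, which is handled as a
binary confound.  The real imaging data are not public; a synthetic-study
generator reproduces the data *structure* so that every stage of the
pipeline is testable end to end.

## Decoding model

Features are the masked voxel values of each subject's coefficient map.
The regression is kernel-based Relevance Vector Regression (RVR): a linear
model `y = Phi m + e`, `e ~ N(0, 1/beta)`, with design `Phi = [1 | K]`,
where `K = Xc Xc^T` is the linear kernel on training-mean-centered
features.  Each weight `m_i` has its own Gaussian prior `N(0, 1/alpha_i)`;
the hyperparameters are estimated by type-II maximum likelihood with the
fixed-point updates

    Sigma    = (A + beta Phi^T Phi)^{-1}
    m        = beta Sigma Phi^T y
    gamma_i  = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / m_i^2
    1/beta  <- ||y - Phi m||^2 / (n - sum_i gamma_i)

Bases whose `alpha_i` exceeds a pruning threshold are removed; the
surviving training samples are the relevance vectors.  The kernel is fixed
to linear because the analysis reports voxel weight maps, which require a
linear decision function; the voxel weights are recovered from the dual
solution as `w = sum_i m_i xc_i` over relevance vectors.

### Numerical choices

* `max_iter = 1000`, convergence when `max |d log alpha| < 1e-3`,
  `prune_alpha = 1e9`, `alpha` initialized to `1/n^2`, `beta` to
  `1/var(y)`.  These are conventional sparse-Bayesian defaults; the
  decoded scale (0–30) is handled by centering `y` and restoring its
  training mean at prediction, and the bias column carries its own
  prunable precision.
* The `beta` update floors the residual sum of squares at
  `1e-10 * n * var(y)`.  Without the floor, exactly noiseless
  (interpolating) fixtures drive `beta` to ~1e11 and the posterior solve
  loses all precision; the floor caps the estimated noise variance at
  1e-10 of the target variance, far below any meaningful resolution.
* A degenerate `n - sum gamma <= 0` is clamped at 1e-10 and blocks the
  convergence flag for that iteration.
* The posterior uses raw LAPACK Cholesky (`dpotrf`/`dtrtri`); the
  permutation test re-fits the model ~1e5 times, so wrapper overhead is
  material.  Singular systems get one jittered retry
  (`1e-8 * trace(H)/m`) before erroring.
* A constant training target short-circuits to an offset-only model, as
  does full pruning of all bases.

Kernel ridge regression (`(K + lambda I)^{-1} yc`) is provided as a
closed-form baseline; in testing it serves as an independent oracle, and
the two methods' cross-validated correlations agree closely on strong
signal, mirroring the no-difference finding among linear kernel methods
this design is based on.

## Cross-validation and metrics

Two schemes: leave-one-out, and k-fold (default k = 4) with fold sizes as
equal as possible (57 -> 15/14/14/14) and a label-balance check — each
fold's scores are t-tested against the remaining scores and the partition
is reshuffled (incrementing the seed, up to 100 attempts) until every
p-value exceeds 0.05.  Per fold the pipeline: computes training feature
means; centers train and test; optionally residualizes the confound
(below); builds the linear kernels; fits RVR; predicts the held-out
subjects; stores the primal weight vector.  Agreement is measured on the
*pooled* out-of-fold predictions by Pearson's r and mean squared error.
Pooling is used rather than per-fold averaging because per-fold r is
undefined for LOO singletons; per-fold correlations are still exposed on
the result object for k-fold schemes.

The final weight map is the across-fold mean of the primal weight vectors
divided by its Euclidean norm, reported unthresholded: every masked voxel
contributes to the prediction, so the map is a representation of the
decision function, not a statistical parametric map.

## Permutation inference

Significance of r and MSE comes from re-running the *entire*
cross-validated procedure with scores permuted across participants
(default 1000 permutations).  The count for r is
`#{ |r_perm| >= |r_obs| }`, for MSE `#{ mse_perm <= mse_obs }`, and the
default p-value is the plain `count / n_perm` ratio; an optional plus-one
correction `(count+1)/(n_perm+1)` avoids literal zeros.  A model is
declared significant only when *both* p-values fall below 0.05.

Two design points deserve note:

* For k-fold schemes the balanced partition is rebuilt against each
  permuted score vector, because the balance t-test references the labels.
  For LOO (label-independent partition) the per-fold kernels are computed
  once and reused across permutations — a pure optimization with
  bit-identical results.
* The confound vector is *not* permuted with the scores: the test targets
  the score–brain association under the observed confound structure.
  Joint permutation is available behind a flag.  Permutations whose
  decoding fails (e.g. collapsed predictions) are counted as beating the
  observed statistic, which is conservative.

## Confound control

A binary medication-like confound is removed with the residual-forming
matrix `R = I − C (C^T C)^+ C^T` (equivalent to dummy-variable regression
/ ANCOVA).  The per-voxel confound coefficients are estimated on the
training fold only and applied frozen to the held-out subjects, so no
test information leaks into training; whole-sample residualization (as
some published analyses do) is available as an explicit replication mode
(`residualize_whole_sample`) applied before model construction.  The design includes an intercept so the binary
regressor removes the group-mean difference.  Residualization applies to
the features only; association between the confound and the *scores* is
assessed separately with a two-sample t-test.

## Pattern localization

Given a labelled atlas on the analysis grid (no resampling; grids must
match), each region's normalized weight is the mean of absolute voxel
weights over the region's masked voxels, `NW(g) = sum_{v in S_g} |w_v| /
|S_g|`.  Regions are ranked by their percentage of the summed NW; the
percentages are scale-invariant and sum to 100 by construction, and a
cumulative column supports top-k share statements.  Ties are broken
lexicographically by region name so tables are deterministic.

## Synthetic studies

The generator emulates the study's data structure, not its physiology:

* **Grid / mask.** 3.1 mm isotropic voxels (matching the emulated
  acquisition); default grid 23x23x18 with an inscribed ellipsoid mask of
  ~5000 voxels standing in for a brain mask at reduced resolution.
* **Planted pattern.** A sum of signed Gaussian blobs (`n_blobs`,
  `blob_sigma_mm`) inside the mask; the unknown true predictive pattern.
* **Scores.** A single latent severity `z ~ N(0,1)` per subject drives
  both time points: the screen-like score is `clip(15.5 + 6.3 z, 0, 30)`
  and the near-scan-like score pushes the same `z` through a half-normal
  quantile transform targeting mean 4.7 / SD 5.4 before clipping — a
  monotone map that reproduces the skew toward low values while keeping
  one ground-truth latent per subject.  A `custom` affine preset and an
  integer-rounding option (totals of integer items) are available.
* **Volumes.** `x_i = z_i w + gain * c_i w_c + noise`, with
  `c_i ~ Bernoulli(0.526)` the binary confound, `w_c` a separate bump the
  confound imprints when `confound_pattern_gain > 0`, and the noise
  spatially smoothed white Gaussian (default FWHM 8 mm, echoing the
  emulated smoothing kernel) rescaled to `noise_sd` per voxel.  Optional
  NaNs (rate per subject-voxel, inside the mask) exercise the
  NaN-intersection mask rule; outside-mask voxels are exactly zero.
* **Confound-score link.** `confound_score_shift` defaults to 0 (the
  motivating sample showed no screen-score/medication association).

What the generator does **not** model: site/scanner effects, task/HRF
structure, spatial nonstationarity, realistic noise spectra, or
registration error.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the stated model, not
performance on real fMRI.

## Validation experiments and problem sizes

`patternreg.validation` holds the standing experiments used by the test
suite and the reproduction script:

* **Recovery** (n = 200, V = 512 on a 16x16x2 grid, three sigma = 10 mm
  blobs, smooth noise at half the blob amplitude): pooled LOO r and the
  weight-map/planted-pattern correlation.  The geometry was chosen by a
  signal-to-noise analysis: smoothing concentrates noise power into smooth
  spatial modes, so recovering the *map* (not just the predictions)
  requires the planted pattern to carry substantially more energy than
  any single noise mode; three broad blobs achieve that while leaving the
  per-voxel noise at a visually realistic half-amplitude.  Two regimes are
  deliberately avoided: very low noise, where the near-interpolating
  kernel fit absorbs residual structure through large dual coefficients
  and the map degrades, and very smooth noise at blob scale, where the
  optimal weights are a noise-whitened version of the pattern and no
  estimator can recover `w` itself.
* **Localization** (same grid, one compact sigma = 6 mm blob planted
  wholly inside one of four atlas blocks): the planted region must rank
  first.
* **Null calibration** (200 independent datasets, n = 40, V = 50, no
  planted signal, 99 permutations each, balanced 5-fold decoding): the
  rejection rate of `p_r < 0.05` and a KS test of p-value uniformity at
  alpha = 0.01.  Five folds rather than LOO keep 200x100 full decoding
  runs within minutes; the calibration property is scheme-agnostic.
* **Algebraic checks** (projector identities, scheme equivalence of LOO
  vs N singleton folds, percentage conservation): exact to 1e-8–1e-10.
* **Study-scale smoke** (defaults: n = 57, V ~ 5000, LOO, 99
  permutations): the full pipeline at the emulated study's shape.

## Known limitations

* The recovered weight map is the model's decision function; under
  spatially correlated noise its population target differs from the
  planted generative pattern (whitening bias), so map-pattern correlation
  is an estimator check on favorable geometry, not a general guarantee.
* Only a single binary confound is exposed end to end (the matrix algebra
  itself handles arbitrary full-rank designs).
* The permutation test treats subjects as exchangeable under the null;
  site or family structure would require restricted permutation schemes
  that are out of scope.
* Atlas handling requires a voxel-exact grid match; no resampling or
  registration is performed.
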