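# Methods

This note documents the models, defaults and numerical choices behind
`restmvpa`, and what the synthetic-cohort experiments do and do not show.

## Preprocessing model

The package models only the *temporal* cleanup of already-aligned volumes:
slice timing, realignment, co-registration and spatial normalisation are
out of scope, and motion regressors enter only as user-supplied confound
columns. The canonical order is linear detrend → nuisance regression
(OLS on `[1, confounds]`) → band-pass. The band-pass is an ideal
frequency-domain filter: rFFT bins with frequency outside `[low, high]`
(default 0.01–0.08 Hz) are zeroed, including DC, so filtered series have
exactly zero temporal mean and the filter is exactly idempotent and
testable bin by bin. Each individual stage is a linear projection and
hence exactly idempotent; the *composed* chain is not perfectly so,
because a least-squares line fitted to band-limited data has a small
in-band component — a second pass changes the series by roughly 2%
relative RMS at T = 120. This is inherent to combining polynomial
detrending with an ideal filter and is asserted at an honest bound in the
tests.

Spatial smoothing is a separable Gaussian with
`σ_vox = FWHM / (voxel_size · 2√(2 ln 2))` per axis (6-mm FWHM default,
zero-padded boundaries, restricted to the mask afterwards; documented
bias at mask edges). Measures are computed on unsmoothed filtered data
and each measure *map* is then smoothed — the conventional ReHo treatment,
applied uniformly to all measures for consistency; both the FWHM and the
stage are configurable. After smoothing, each map is z-scored across the
mask per subject for cross-subject comparability (configurable; note this
makes a strictly focal effect shift the map's global mean slightly, so
out-of-region voxels acquire a small opposite-signed group difference —
visible in the synthetic recovery runs as larger univariate masks).

An option to discard initial volumes at load (`drop_initial`) mirrors the
usual dummy-scan handling; the synthetic generator produces stationary
series, so its default is 0.

## Measures

* **ReHo**: Kendall's W over the voxel plus its 6/18/26-connected
  neighbours (default 27-voxel cluster). Ranks use mid-ranks for ties with
  no tie correction (ties have measure zero for continuous data). Edge
  voxels use their available in-mask neighbours with K adjusted; a strict
  mode zeroes incomplete neighbourhoods instead (REST-compatible).
* **ALFF/fALFF** run on detrended but *unfiltered* series. The one-sided
  amplitude spectrum is `a(f) = √power`; ALFF is the band mean, fALFF the
  band/full amplitude-sum ratio. The full band is `(0, Nyquist]`: at
  TR = 3 s the Nyquist frequency is 0.167 Hz, so a literal 0.25 Hz cap
  would be physically unattainable; a lower cap is available as an
  override. All-zero series get fALFF = 0 with a logged flag.
* **Degree centrality** sums *signed* supra-threshold correlations
  (r > 0.25 by default), so anticorrelations never contribute; a binary
  (count) mode exists for comparison. The map is z-scored over the mask.
  Computed blockwise so the V × V correlation matrix is never stored.
* **Seed connectivity** clips r to ±(1 − 10⁻⁷) before atanh so seed
  voxels themselves stay finite. Seeds are user-supplied masks or
  coordinate spheres (mm or voxel space; default radius 6 mm); no atlas is
  bundled, and sphere membership is by voxel-center distance, which makes
  the resolved sets exactly enumerable in tests.

Feature concatenation orders columns by measure (ReHo, fALFF, ALFF, DC,
then seed maps) and voxel linear index, with per-column provenance kept
for recovery scoring and reporting.

## Feature selection

Univariate stage: pooled-variance two-sample t per voxel, two-tailed,
thresholded at the exact Student quantile for the fold's degrees of
freedom rather than a fixed printed cutoff (at df = 207 and α = 0.05 the
quantile is 1.9715, matching the familiar reference value). Cluster-extent
correction simulates `n_iter` Gaussian-noise volumes (default 1000),
smooths them to the analysis FWHM, re-standardises over the mask,
thresholds two-tailed at the voxel α and records the maximal
supra-threshold component; the minimum cluster size is the smallest s with
`P(max ≥ s) ≤ α_cluster`. Smoothness is parameterised by the applied
FWHM, not estimated from residuals. Connectivity default is 26
(configurable 6/18/26). Because the simulation depends only on the mask,
FWHM and α levels, it is computed once per run and shared by all folds —
numerically identical to running it per fold. Each measure keeps its own
surviving voxels; a fold where no measure survives raises an explicit
error suggesting a weaker threshold.

Multivariate stage (training rows only, after z-scoring columns by
training statistics):

* **SVM-RFE** uses a linear SVM and the w_j² criterion — the canonical,
  reproducible form — even when classification later uses an RBF kernel;
  a kernel hook can replace the criterion. Elimination step: 1 while ≤ 500
  features remain, otherwise 10% per round (configurable); ties in w_j²
  eliminate the lower column index first, making rankings run-to-run
  identical. The kept count k is chosen from a configurable grid by inner
  stratified CV accuracy of a linear SVM, ties to the smallest k.
* **LASSO** regresses the 0/1 labels as a continuous response; the path
  is solved by coordinate descent over a log-spaced grid from the
  closed-form λ_max downward, λ* minimises inner-CV MSE, and kept features
  are the nonzero coefficients at λ*. λ = 0 falls back to a least-squares
  solve.

## Classifiers

The ELM codes targets ±1, draws input weights and biases from
Uniform(−1, 1), and solves `β = H⁺y` with the pure Moore–Penrose
pseudoinverse (an optional ridge ε exists for ill-conditioned H). The
decision is sign(Hβ) with sign(0) → +1. The hidden-node count is tuned
over a grid (default 1…400) with the inner-CV accuracy averaged over
`n_repeats` (default 100) seeded initialisations, ties to the smallest L.
Because any single random initialisation can leave stray errors near the
interpolation threshold, held-out predictions come from the majority vote
of the `n_repeats` final models at the chosen L (ties → +1); the tuning
criterion remains the averaged single-model accuracy. The sigmoid is the
standard `1/(1+e^{−z})`.

SVM baselines are standard linear/RBF SVMs tuned by exhaustive grid search
over eight-point logarithmic C and γ grids (10⁻³…10⁴), ties to the
smallest C then γ. Inner CV everywhere is stratified k-fold on training
data (default 5 folds, capped by the smaller class size).

## Evaluation

Outer CV is leave-one-out or stratified k-fold with a recorded seed
(stratification prevents class-empty folds at small n). Measure maps are
per-subject unsupervised quantities and are computed once for the cohort;
every supervised stage (t mask, cluster rule application, RFE/LASSO,
classifier tuning) is refit per fold on training rows only, which the
tests verify by corrupting held-out rows and checking the fitted
artifacts are unchanged. Metrics are reported per fold and as mean ± SD
across folds; zero-denominator metrics (e.g. PPV in a LOO fold with no
positive call) are flagged undefined and excluded from the mean with an
exclusion count, and pooled-count metrics over all test decisions are
reported alongside. The permutation test permutes the pooled test labels
against the fixed predictions (P = 1000 default) — it tests the labeling
given the predictions, not the full pipeline; re-running the pipeline per
permutation would be the stricter variant and is intentionally not the
default.

## Synthetic cohorts

The generator emulates two-group resting-state acquisitions at desk
scale: AR(1) Gaussian voxel noise (φ = 0.3, unit SD — a closed-form
temporal spectrum that band-limited analyses can be checked against) on a
24³ grid of 3-mm voxels, 120 volumes at TR = 3 s, 20+20 subjects by
default. Effects are additive band-limited latent signals whose amplitude
differs by group: a *coherence* effect shares one latent across a region
(expected within-region pairwise correlation `a²/(a²+σ²)`), an *amplitude*
effect draws an independent latent per voxel, and a *coupling* effect
shares a latent between a region and a partner region. Planted amplitudes
default to 3× the noise SD in the test cohorts — chosen for pipeline
testability, not biological realism. The generator writes ordinary NIfTI
files plus a manifest and a ground-truth JSON of planted voxel sets, and
is bitwise reproducible from its seed.

What passing tests show: the pipeline is leak-free, calibrated under the
null (≈5% univariate retention at α = 0.05, chance-level CV accuracy),
and recovers strong focal effects (100% outer-CV accuracy and ≥ 0.85
planted-voxel recall in the shipped runs). What they do not show:
performance on real BOLD data with hemodynamics, motion, physiological
noise, scanner effects or realistic effect sizes — none of which are
simulated.

## Problem sizes and defaults in the shipped experiments

The package defaults follow the method's reference configuration (ELM
grid 1…400 with 100 repeats, 1000 Monte-Carlo iterations, 1000
permutations, eight-point SVM grids). The test suite and
`scripts/acceptance.py` run reduced ELM grids (a few L values, 10
repeats), 3-fold inner CV and 5-fold outer CV on the 20+20 cohort — sizes
chosen so the whole suite runs on a single CPU in minutes while leaving
every qualitative property intact. Calibration runs use unsmoothed maps
(FWHM 0) so voxel noise stays independent and the binomial argument for
the retention interval is exact.

## Known limitations

* The permutation default inherits the "fixed predictions" design; its p
  floors at 1/(P+1) and does not account for selection variability.
* Per-subject map z-scoring couples focal effects to the global mean
  (see above); turn it off for strictly focal inference.
* Cluster-extent smoothness is taken from the applied FWHM; residual
  smoothness estimation is not implemented.
* The ELM solve is exact but unregularised by default; for nearly
  collinear hidden layers enable the ridge option.
* Binary (two-group) classification only.
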