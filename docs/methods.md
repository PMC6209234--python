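# Methods

## Signal model

A subject's resting-state BOLD recording is treated as a noisy linear
mixture: for voxel *i*,

    x_i(t) = Σ_k A[t,k] s_k(i) + η_i(t),     η ~ N(0, σ² I),

where the `s_k` are spatially independent source maps, `A` is the
mixing matrix of activation time courses, and the noise is isotropic
Gaussian. The pipeline estimates the sources from a temporally
concatenated group of subjects, then projects every subject onto them.

### Group decomposition (`rsdiag.decomposition`)

`temporal_concat` demeans and variance-normalises each voxel series per
subject (standard for temporal-concatenation group ICA, where
between-subject amplitude differences would otherwise dominate the
covariance) and stacks subjects along time.

`fit_group_pica` implements noisy ICA in four steps:

1. PCA of the (time × time) covariance; the model order K fixes the
   retained subspace. K defaults to the atlas size (34).
2. The isotropic noise variance σ² is initialised as the mean of the
   discarded eigenvalues, and whitening uses the noise-shrunk
   eigenvalues √(λ_k − σ²) — the probabilistic-PCA correction.
3. A fixed-point negentropy-maximising rotation (FastICA, logcosh
   contrast, seeded and deterministic) separates the whitened spatial
   maps.
4. The residual of the mixture fit re-estimates σ², and steps 2–3
   repeat until σ² changes by less than `tol` (relative, default 1e-4)
   or `max_iter` (20) is reached; non-convergence is flagged with a
   warning, never silently.

Estimated sources are normalised to unit variance and sign-fixed to
positive skewness. ICA determines sign arbitrarily; blob-like
activation maps have positive skew, so this convention makes atlas
matching and source-recovery checks well-defined.

`dual_regression` is two-stage least squares: subject time courses from
regressing each frame on the group maps, subject maps from regressing
each voxel series on those time courses. Rank-deficient designs raise
an error naming the collinear components (an all-zero subject therefore
errors at stage 2 rather than returning zeros). On data lying exactly
in the span of the group maps the recovery is exact (projection
idempotence), which the tests assert to 1e-9.

`group_difference_test` summarises each subject map as its mean value
within an optional component mask (default: all voxels — the phantom
maps are dense, and the statistic is deliberately simple), permutes
group labels, and reports two-sided add-one p-values
p = (1 + #{|perm| ≥ |obs|}) / (1 + n_permutations) with Bonferroni
correction at α/K.

`smooth_gaussian` applies per-frame 3D Gaussian smoothing with
σ = FWHM / (2√(2 ln 2)) voxels (FWHM default 2 mm; at 1 mm voxels
σ ≈ 0.8493). Smoothing is off by default in the phantom pipeline since
the phantom injects no inter-subject anatomical variability.

### Atlas (`rsdiag.atlas`)

The registry merges four local parcellations into 34 named cortical
components (10 parietal: 5 SPL + 5 IPL; 2 TPJ; 12 ventral frontal; 10
dorsal frontal). The reference component names and anatomical labels
ship as the default metadata table; the geometry comes from a label
volume (real atlases in practice, generated blob layouts in tests).

Matching assigns each atlas area the spatial map with the largest
Pearson correlation between the z-scored binary area mask and the
z-scored map over in-brain voxels. The relation is deliberately
non-injective (an area picks its best map; a map may serve several
areas), ties break toward the lowest map index, zero-variance maps are
excluded with a warning, and correlations keep their sign.

### PSD features (`rsdiag.spectral_features`)

Features are one-sided power spectral densities of the matched area
time courses. The default estimator is the full-length, mean-removed
periodogram: it is *exactly* invariant to circular time shifts — the
property that makes PSDs attractive for comparing activations occurring
at different latencies across subjects — and satisfies Parseval
(Σ power · Δf = variance) to numerical precision. Welch averaging is
available (`estimator="welch"`) but trades away exact shift invariance.
Cohorts with mixed repetition times (2 s and 3 s scans in the source
studies) are interpolated onto a common grid spanning 0 to the smaller
Nyquist frequency, 32 bins by default. Features are raw density values;
log-transform and unit-sum normalisation are off by default.

### Per-area classifiers (`rsdiag.area_classifiers`)

Each of the 34 areas has its own sparse autoencoder and SVM.

The autoencoder is a single sigmoid hidden layer with a linear decoder,
trained by L-BFGS on the full batch with analytic gradients under the
objective

    L = ½·mean‖x̂ − x‖² + β Σ_j KL(ρ ‖ ρ̂_j) + λ (‖W_enc‖² + ‖W_dec‖²),

where ρ̂_j is hidden unit j's mean activation over the batch, clamped
to (1e-8, 1−1e-8) before the KL. Initialisation is seeded
symmetric-uniform scaled by fan-in, so training is deterministic.
Hyper-parameter ranges follow the reference grid (hidden 10–100,
ρ 0.05–0.9, β 1–20, λ 1e-6–1e-3); `grid_search_sae` minimises held-out
reconstruction error in lexicographic grid order. Defaults are
ρ = 0.5, β = 1, λ = 1e-4: reconstruction error — the reference search
metric — favours weak sparsity, and an aggressive target (ρ ≈ 0.1 with
β ≥ 3) measurably collapses the encoded group separation. Depth is 1
(the smallest architecture consistent with the design); the ensemble
uses hidden size 8 on 32-bin inputs.

The SVM is a soft-margin RBF classifier with
K(u,v) = exp(−‖u−v‖²/s²), s the kernel scale (default 5) and box
constraint C (default 12) — the reference operating point. Class
membership is the logistic sigmoid of the signed decision value,
oriented so positive means autism: score(x) = 1/(1+e^(−d(x))) ∈ (0,1),
with no Platt scaling (slope 1, the literal sigmoid-of-distance rule).
`grid_search_svm` maximises validation accuracy over the reference
ranges, ties toward the smallest scale then the smallest box.

Within the ensemble each area's 32 feature bins are standardised with
training-set statistics before encoding; the scaler is frozen into the
fitted model.

### Screening and fusion (`rsdiag.diagnosis_fusion`, `rsdiag.pipeline`)

An area is *significant* when its stand-alone sensitivity and
specificity both exceed 0.65 (strictly). Performance is computed from
membership scores thresholded at 0.5 (score ≥ 0.5 calls ASD). The
screen runs on training data only and is frozen before any test subject
is scored; by default the per-area sensitivity/specificity come from
internal 4-fold out-of-fold scores *within* the training set
(`selection_cv=4`), because the flexible kernel classifier memorises
training subjects and in-sample rates would pass nearly every area. An
empty selection falls back to all areas with a warning.

The global diagnosis is winner-takes-all: the mean membership score
over the significant areas; ASD iff the mean exceeds 0.5, with an exact
tie resolved conservatively to TD. The personalized report presents the
raw scores (no rescaling, absolute [0,1] scale) with 8 equal-width
blue-to-red bins, half-open except the last.

### Evaluation (`rsdiag.evaluation`)

Stratified 2/4/10-fold and leave-one-subject-out CV re-fit the full
ensemble, including the screen, per training fold; accuracy,
sensitivity and specificity pool the out-of-fold diagnoses and AUC
pools the fused scores. `repeat_cv` summarises accuracy over
independently re-folded repetitions (default 100). `holdout_split`
produces a stratified 60/15/25 partition with largest-remainder
rounding. `predictive_values` maps (sens, spec, prevalence) to PPV/NPV
with the standard Bayes formulas at the two default prevalences 1/68
(general population) and 0.187 (high-risk siblings). At prevalence
1/68 with any sensitivity/specificity near 0.9 the formulas put NPV
≈ 0.999: almost everyone is a true negative at a 1.5% prevalence.
This package always reports the formula values.

`permutation_test` assesses significance by shuffling the labels the
classifiers train on and repeating the same evaluation scheme (default
4-fold CV), with p = (1 + #{shuffled acc ≥ observed}) / (1 + 99). The
evaluation is CV-based rather than a single small hold-out because with
a 10-subject test set a lucky shuffle can tie a perfect observed
accuracy, making the attainable minimum p = 0.01 unreachable; pooling
all subjects removes that artifact. All randomness descends from one
root seed through spawned seed sequences.

## Synthetic phantoms (`rsdiag.phantom`)

The generator emulates exactly the structure the pipeline assumes:

- **Geometry** — disjoint, contiguous spherical blobs placed on a
  lattice with seeded jitter, one per atlas label; source maps are
  smooth positive weights decaying from each blob's centroid.
- **Dynamics** — zero-mean band-limited time courses (random-phase
  Fourier modes in 0.01–0.08 Hz, the resting-state band) scaled so the
  series variance equals the requested in-band power (baseline 1.0).
- **Group effect** — ASD subjects' affected areas carry in-band power
  multiplied by (1 + effect_size · gain), gain ~ U(0.5, 1.5) per
  subject. The effect lives in spectral power, the feature space the
  classifier consumes, not in the signal mean; effect_size = 0 makes
  the groups exchangeable by construction.
- **Behavior** — ASD subjects receive an ADOS-like score
  a + b·(summed injected effect) + N(0, sd²) with a = 8, b = 1,
  sd = 1, so the sign of score/behavior correlations is recoverable.
- **Noise** — i.i.d. Gaussian per voxel (σ default 0.5, i.e. half the
  baseline source amplitude). No motion, drift, slice-timing or
  physiological noise is simulated: the pipeline consumes preprocessed,
  co-registered volumes, and those artifacts belong to preprocessing.

Everything is a pure function of the `PhantomSpec`, bit-identical under
a fixed seed.

**What passing phantom tests do not show:** phantoms have no
anatomical variability, no registration error, no temporal
autocorrelation beyond the band limit, and a literal one-to-one
source↔area correspondence. Recovery and accuracy results on phantoms
validate the machinery — decomposition, matching, feature extraction,
screening, fusion, evaluation — not clinical performance on real
cohorts, whose headline numbers come from controlled-access data this
package does not ship.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale cohorts chosen as
realistic-but-small study conditions: 40 subjects (20/20) with 10 areas
on a 12×12×6 grid and 100 frames at TR 2 s for recovery and
significance checks; 6 subjects with the full 34 areas on 30×30×12 for
the model-order check. The noise-variance loop tolerance is 1e-4
(relative); FastICA runs at tol 1e-5, max 500 iterations; L-BFGS at
ftol 1e-6, max 500 (150 inside the ensemble); the KL clamp is 1e-8.
Degenerate inputs are contracts, not crashes: constant series yield
zero spectra with a warning, zero-variance maps are excluded from
matching with a warning, single-class training sets and rank-deficient
designs raise named errors.

## Known limitations

- The significant-area screen needs enough training subjects for its
  internal folds (min class count ≥ 4 by default); below that it falls
  back to in-sample rates, which over-select.
- Model order is fixed, not estimated; no automatic dimensionality
  selection and no mixture-model thresholding of component maps.
- The CLI `features` stage recomputes atlas matching from the stored
  group maps; it assumes the label volume and maps share a grid.
- Welch PSDs break exact shift invariance (documented trade-off).
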