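# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limits of the `neurochron` pipeline.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Brain-age model

**Features and kernel.** Each subject's grey-matter (GM) and
white-matter (WM) probability volumes are smoothed with a separable
Gaussian (default FWHM 4 mm; σ = FWHM / (2√(2 ln 2)) per axis,
zero-padded boundaries, so interior mass is conserved), flattened in a
fixed raster order (axis 0 fastest) and concatenated GM-then-WM. No
brain mask or feature pruning is applied by default (an optional mask
would simply restrict the voxel set; only dot products of identically
ordered vectors matter). The similarity of subjects i, j is the dot
product `K[i,j] = x_i · x_j`.

**Gaussian-process regression.** Ages are modelled as
`y ~ N(μ1, σ_f² K̃ + σ_n² I)` with `K̃ = K / mean(diag K)` and
`μ = mean(y)`. The kernel normalisation plus the free signal variance
make predictions invariant to any overall rescaling of the features
(verified to 1e-6 in the tests). Hyperparameters `(σ_f², σ_n²)` are
optimised in log-space on the exact log marginal likelihood. Because
raw probability maps have a large DC component, the kernel has one
dominant eigenvalue and the likelihood surface is badly conditioned; a
single descent start can stall in a noise-only optimum. The optimiser
therefore scans a fixed coarse grid (13 × 9 points in
`log σ_f² ∈ [−10, 14]`, `log σ_n² ∈ log var(y) + [−10, 3]`) — cheap,
because the likelihood is evaluated in the kernel eigenbasis at O(n)
per point — and polishes the best cell with L-BFGS using analytic
gradients. The procedure is deterministic. A jitter of 1e-8 is added
to the normalised covariance diagonal.

**Cross-validation and permutation test.** Fold assignment shuffles
subject indices with the run seed and deals round-robin (sizes differ
by ≤ 1); it depends only on (n, k, seed), never on the ages, so
held-out labels cannot leak into it. Each subject's prediction comes
from a model fitted without its fold. Accuracy is Pearson r, R²
(reported as r², consistent with quoting r and percent variance as a
pair), MAE and RMSE. The permutation test permutes age labels,
recomputes the cross-validated r per permutation, and reports
`p = (1 + #[r_perm ≥ r_obs]) / (n_perm + 1)`; the smallest attainable p
is `1/(n_perm+1)`. Hyperparameters are re-optimised per permutation by
default; the fixed-hyperparameter mode (used for the large calibration
runs) fixes `(σ_f², σ_n²) = (1, var(y))`, which is permutation-invariant,
so exchangeability under the null is exact. Per-fold eigendecompositions
of the kernel are cached and reused across label vectors, which is what
makes 100 cross-validated fits per replicate affordable.

**Brain-PAD.** `brain_pad = brain_predicted_age − age`; positive =
"older-appearing". A one-sample t-test of DS brain-PAD against a
user-supplied reference mean (default 0, the expectation under unbiased
cross-validation) accompanies the group model.

## PET kinetics

**Schedule and frame averaging.** The standard acquisition is 58
frames over 90 min (18×5 s, 6×15 s, 10×30 s, 7×60 s, 4×150 s,
13×300 s), half-open intervals `[start, start+duration)` tiling from
zero. Fine-grid curves (default Δt = 1 s) are frame-averaged as the
trapezoidal integral over the frame divided by its duration — second-
order accurate, so a 10×-finer grid changes frame values by < 0.1%.

**TAC extraction.** An ROI TAC averages voxels with the ROI label and
GM probability ≥ 0.65 (reference region: superior cerebellum at
≥ 0.90, boundary inclusive). Each voxel's TAC is divided by
`1 − CSF probability` *before* averaging (voxelwise partial-volume
correction; ROI-level correction would differ and is deliberately not
used). Voxels with CSF probability > 0.95 are excluded rather than
divided, since dividing by ≈ 0 amplifies noise; exclusions are counted.
Default fit weights are the frame durations (longer frames integrate
more counts).

**Basis-function SRTM.** The simplified reference tissue model is
`C_T = R₁C_R + θ₂ · C_R ⊗ e^{−θ₃ t}` with `θ₂ = k₂ − R₁k₂ₐ`,
`θ₃ = k₂ₐ = k₂/(1+BP_ND)`. θ₃ is gridded (default 64 log-spaced values
in [0.006, 0.6] min⁻¹, the standard range for PiB); for each grid value
the convolution basis is computed on the fine grid (trapezoidal
discrete convolution via FFT with end corrections) and frame-averaged,
(θ₁, θ₂) are solved by weighted linear least squares, and the grid
point minimising the weighted residual sum of squares wins. Reported:
`R₁ = θ₁`, `k₂ = θ₂ + θ₁θ₃`, `k₂ₐ = θ₃`, `BP_ND = k₂/k₂ₐ − 1`.
Negative fitted BP_ND is allowed but flagged. The fine reference curve
is the measured reference frames interpolated linearly through their
midpoints (anchored at the origin); callers holding a noiseless fine
curve can pass it directly. Fits are scale-invariant (both TACs × c
leaves all rates unchanged, WRSS scales by c²) and, on noiseless
forward curves, recover BP_ND ∈ [0.2, 2] within 2% despite the ~7% grid
spacing, because the linear coefficients absorb most of the θ₃
quantisation.

## Amyloid status

**Positivity.** Striatal BP_ND (unweighted mean over left/right caudate
and putamen) is bimodal in DS. A subject is PiB-positive iff their
striatal BP_ND is at least σ₀ ("one SD from zero"; the boundary is
positive). By default σ₀ is the sample SD of the full bimodal striatal
distribution (`sd_mode="cohort"`): with a tight negative mode at zero
and an elevated positive mode this lands the cut between the modes.
Two alternatives are exposed: `"fixed"` (user-supplied σ₀) and
`"iterative"` (re-estimate σ₀ as the RMS about zero of the
currently-negative subjects until the labels stabilise). The iterative
scheme is **not** the default for a structural reason: truncating at
the threshold biases the RMS low, and its fixed point sits at ≈ 0.84 of
the negative component's true SD, inside the negative upper tail —
about 20% of true negatives end up misclassified regardless of how
tight the negative component is. More generally, any rule that sets the
threshold at exactly one negative-component SD leaves the ~16% upper
tail of the negatives above it; only a between-modes cut can recover
the generating labels at the ≥ 95% level, and the cohort SD is the
simplest estimator of such a cut. The output records which mode and σ₀
were used.

**Regional abnormality.** Per ROI, the mean and SD are computed over
PiB-negative subjects; a value ≥ mean + 2 SD is abnormal (boundary
inclusive; with a degenerate SD of 0 the rule reduces to ≥ mean, so
exact equality still flags). Abnormal ROIs are counted over the 30-ROI
catalogue (22 cortical, 4 striatal, 4 other subcortical; the cerebellar
reference is never counted), and mean cortical BP_ND averages the
cortical entries. The catalogue ships as an editable CSV structure so
any 30-ROI atlas can be slotted in.

## Association models

All estimators are thin wrappers over statsmodels/scipy, validated
against closed-form or brute-force oracles in the tests: OLS with Wald
t CIs; binary logistic regression by ML (Newton, with a BFGS fallback
and a flag under complete separation); proportional-odds cumulative-
logit ordinal regression (thresholds strictly increasing by the
parameterisation); Welch's t by default (Student optional); Pearson
correlation with t-based p; Fisher's exact test (two-sided,
point-probability method). A binary-predictor OLS coefficient equals
the difference of group means exactly. Missing CAMCOG is handled by
listwise deletion per model. No multiple-testing correction is applied
by default (raw p-values; Benjamini–Hochberg available in config).

`run_cohort_models` fits a fixed, documented battery of 12 entries
(group effects on brain-PAD and ICV; logistic PiB-status; linear
amyloid-burden models with age as covariate; CAMCOG models including
the brain-PAD × PiB interaction; the ordinal CAMDEX model; the
CAMDEX-stable subgroup contrast; per-group brain-PAD ~ ICV
correlations; sex and APOE t-tests).

## The synthetic cohort

The generator emulates exactly the structure the analysis assumes, not
real anatomy:

- **Tissue maps.** On a 12×14×12 grid at 1.5 mm (the smallest grid
  where smoothing and vectorisation are non-trivial while keeping
  kernels sub-second), `GM = clip(g₀ − atrophy_rate · age_eff ·
  pattern + ε, 0, 1)` over fixed smooth fields, WM at half the rate,
  CSF the remainder. `atrophy_rate` defaults to 0.003 probability/year
  (so max-age decline stays below the dynamic range), voxel noise SD
  0.02. Effective age = chronological age + group offset (8 y for DS,
  near the adjusted effect the design targets) + a per-subject
  deviation `N(0, 7²)` years. The deviation is essential: without it
  the true brain-PAD is constant within each group and the CAMCOG
  interaction would be unidentifiable; 7 y is chosen to match the
  reported DS brain-PAD spread (~8 y including measurement error).
  Head-size differences are emulated by shrinking only the CSF
  compartment (DS intracranial volume ≈ 84% of controls), leaving the
  GM/WM features — and hence the age signal — untouched.
- **PET.** The reference curve is an analytic shape-2 gamma variate
  (peak at 300 s) — positive, with a realistic early peak, and exactly
  integrable, so frame-averaging oracles exist. Target TACs come from
  the SRTM forward model with per-subject R₁ ≈ 0.9, k₂ ≈ 0.15 min⁻¹ and
  per-ROI true BP_ND; frame noise is Gaussian with SD `cv · value /
  √(duration/max duration)` (short early frames noisier), default CV
  5%. Striatal BP_ND is a two-component mixture: negatives N(0, 0.05²),
  positives N(0.5, 0.12²) (≥ 4 pooled SDs apart, so the bimodality the
  classifier relies on is real), positive fraction 19/46. Positive
  subjects draw a cortical mean from N(0.36, 0.22) (floored at 0.05)
  with per-ROI scatter; negative subjects' non-striatal ROIs carry
  *bounded*, U-shaped trace noise (0.03 × Beta(0.3, 0.3)) rather than
  Gaussian noise — a bounded distribution is the only way a 2-SD
  abnormality cut can be essentially never exceeded by true negatives,
  which is the empirical behaviour the classification stage expects.
- **Cognition.** `CAMCOG = 85 − 1.75 · brainPAD_true · 1[PiB+] +
  N(0, 7²)`, clipped to [0, 107]; ~3/46 DS subjects are missing CAMCOG
  (cannot complete the assessment). CAMDEX class probabilities differ
  by PiB status (positives mostly declining/dementia). PiB-positive DS
  subjects are drawn older than negatives, reproducing the age
  dependence of amyloid.
- **Determinism.** Per-subject streams are seeded `seed + index` (map
  and TAC noise at fixed large offsets), in the fixed order train, DS,
  control — adding subjects never perturbs earlier subjects' draws.
  Replicated experiments must therefore space their base seeds by more
  than the generator's internal span (the tests use a stride of
  350,003); adjacent integer seeds produce correlated cohorts.

**What the generator does not emulate** — hence what passing tests do
*not* show about real data: no scanner effects, motion, registration
error or real anatomy; amyloid status is coupled to age but not to
brain-PAD itself, so the (real-data) positive logistic association
between brain-PAD and PiB status is structurally absent from synthetic
cohorts (the logistic machinery is validated by oracle equivalence
instead); regional BP_ND noise models are stylised; CAMCOG has no
floor/ceiling psychometrics beyond clipping.

## Problem sizes and calibration checks

The acceptance script and the acceptance-grade tests use: noiseless
SRTM round trips at BP_ND ∈ {0.2, 0.5, 1, 2}; 200 noisy-fit replicates
at 5% frame CV (median relative bias ≤ 5%); one default cohort
(n_train = 300) for cross-validated accuracy (r ≥ 0.9, MAE below the
chance MAE of always predicting the mean age); 50 replicate cohorts for
offset-recovery coverage (group coefficient within 2 SE of the 8-year
truth in ≥ 90%); 200 null replicates of the 99-permutation test on a
30-subject kernel (p-values uniform by KS at α = 0.01; minimum p
exactly 1/100); 2000 classification replicates at the mixture
N(0, 0.05²) / N(0.4, 0.15²), n = 46 (mean agreement ≥ 95%); estimator
oracles on ≤ 10-row instances (agreement within 1e-8); and one
default-cohort imaging-path interaction recovery plus 200 null
replicates for the type-I rate (inside the binomial 95% band around
0.05). These sizes keep the whole suite at roughly a minute on one CPU
while leaving the Monte-Carlo margins comfortable.

## Known limitations

- Mean-only GP predictions; the predictive variance is computed
  internally but not reported.
- R² is the squared Pearson correlation, not 1 − SSE/SST (both are
  computable; r² is the headline to keep the r/R² pair consistent).
- The basis-function fit reports the grid θ₃, not a continuously
  refined one; with the default 64-point grid the induced BP_ND error
  is below 2% on noiseless curves, which is adequate relative to the
  noise-induced spread at realistic frame CV.
- Wald confidence intervals throughout (profile-likelihood intervals
  for the logistic models are a possible extension).
- No SRTM2/Logan/voxelwise parametric imaging; no image registration,
  segmentation or atlas construction — the pipeline consumes
  already-normalised maps and labels.
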