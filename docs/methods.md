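# Methods

## Generative model

The synthetic cohort emulates a three-group SIN study (OM, ONM, YNM; default
24 subjects per group). Each subject's voxel-wise connectivity map on an ROI
grid (default 12×12×12 voxels, 2 mm isotropic, RAS+ affine with origin 0) is

```
map_i = T(peak shift) + a_g + A_i + h_g * F_i + e_i
```

* `T` — isotropic Gaussian bump (peak amplitude `template_amplitude`,
  default 1; FWHM `template_width_mm`, default 8 mm). A bump is the simplest
  shape with a well-defined peak, which the centroid-shift statistic needs.
* `a_g` — group amplitude offset (`amplitude_offset`), the "upregulation"
  dial.
* `A_i ~ N(0, amplitude_sd²)` — per-subject scalar amplitude (default
  SD 0.3). Without it, between-subject variance of ROI summaries is limited
  to the spatial average of the smooth field, which is unrealistically small;
  with it, bootstrap CI widths and mixed-model variance components are on the
  scale real cohorts show.
* `h_g * F_i` — smooth subject-specific field: white noise Gaussian-filtered
  at σ = 1.5 voxels, normalised to unit SD, scaled by `heterogeneity_sd`.
  A smooth (not i.i.d.) field is required for within-group ISPC to be a
  meaningful dial — i.i.d.-only subject noise drives within-group ISPC to a
  degenerate value near 0.
* `e_i ~ N(0, noise_sd²)` — i.i.d. voxel measurement noise.

Group-level effects are injected through `peak_shift_mm` (template peak
displacement, e.g. +4 mm on z for the older-non-musician superior shift) and
through the behaviour model
`accuracy_i = intercept + slope · summary_i + N(0, behavior_noise_sd)`,
clipped to [0, 1], where `summary_i` is the subject's top-40% ROI mean.
When several measures are generated (task connectivity and resting
connectivity), the subject amplitude and smooth field of different measures
share a common component with correlation `cross_measure_corr` (default 0.5):
a subject's task and resting maps are related but not collinear, so the
resting covariate in the brain–behaviour regression is informative without
destroying the partial slope.

BOLD simulation: the seed series is the HRF-convolved stimulus stream plus
white noise; the target is `baseline_coupling · seed` plus, per condition,
`amplitude_c · (seed − mean)(x_c − mean)` — the same interaction construction
the estimator models — plus independent noise. The task design generator
reproduces the study structure exactly: 4 blocks × 60 trials (3 SNR × 4
syllables × 5 repetitions, shuffled within block), 0.4 s stimuli, ITIs drawn
from {4.0, 4.5, 5.0, 5.5, 6.0} s, TR 0.64 s.

### What the generator does not emulate

No scanner drift, motion, physiological noise, spatial autocorrelation of
measurement noise, or hemodynamic variability across subjects/regions.
Passing tests therefore show that the *estimators and statistics* are
correct and calibrated under a clean generative model — not that the
pipeline is robust to real-data artefacts (those are handled by upstream
preprocessing, which is out of scope).

## Estimators

**gPPI.** Interaction regressors are formed at the BOLD level by default:
demeaned seed × mean-centred HRF-convolved condition regressor. Published
gPPI pipelines differ between BOLD-level and "neural-level"
(deconvolve, gate, reconvolve) construction; BOLD-level is deterministic and
reproducible, so it is the default, and a `neural` mode (regularised Wiener
deconvolution, regularisation 0.1, gated by the raw stimulus indicator and
reconvolved) is available; the mode is recorded in outputs. Conditions are
SNR-pooled by default (three interaction terms); a 12-regressor
syllable×SNR mode exists. The HRF is the canonical double-gamma (peak 6 s,
undershoot 16 s, ratio 6), peak-normalised, sampled at TR with 16×
oversampling of the stimulus box-car. Per-voxel fits are ordinary least
squares on uncensored rows; motion censoring is a caller-supplied row mask.
Zero-variance target voxels yield NaN coefficients and a `valid=False` flag,
never a silent zero.

**RSFC.** Nuisance regression (OLS projection) precedes filtering; the
band-pass is a 4th-order Butterworth applied forward-backward (zero phase).
One cycle of the low cutoff (capped at a quarter of the series) is trimmed
from each end before the Pearson correlation: `filtfilt` edge transients
otherwise leak out-of-band power into the estimate (measurably so for a
strong out-of-band sinusoid).

## Statistics

* **Top-fraction summarization**: k = ceil(fraction·V); ranking by the
  cross-condition mean map so the voxel set is condition-independent; ties
  broken by ascending voxel linear index (deterministic, permutation-safe).
* **Outlier replacement** (per group × ROI × condition × measure): points
  beyond 2 sample SD (candidate included, ddof=1) replaced by the group
  median of the original values. Zero-SD groups are untouched.
* **Mixed ANOVA**: pingouin's implementation; Greenhouse–Geisser correction
  applied to within/interaction terms when Mauchly's test rejects at 0.05
  (ε = 1 exactly for two within levels). FDR (Benjamini–Hochberg, via
  statsmodels) is applied by the caller across the ROIs of a hemisphere per
  measure; post hoc families are corrected separately.
* **Linear mixed model** `value ~ group + (1|subject) + (1|region)`: REML via
  statsmodels MixedLM with crossed variance components (a single group and
  `vc_formula` for subject and region). The optimizer cascade is
  powell → cg → lbfgs: the default BFGS reports spurious non-convergence and
  biased variance components on this structure, while powell/cg reproduce
  lme4's REML solution. The optional robust mode iteratively Huber-clips
  response residuals (c = 1.345, MAD scale) around the current fit —
  an IRLS-style downweighting of outliers — and is off by default; parameter
  recovery holds either way.
* **Bootstrap difference of differences**: whole subjects are resampled with
  replacement within group at the original n (fixed draw order ONM, OM, YNM),
  preserving cross-ROI correlation; per-ROI group-mean differences are
  averaged over the ROI set; the 95% CI is the 2.5th/97.5th percentile with
  linear rank interpolation. Percentile, not BCa, by design.
* **ISPC**: Pearson over ROI voxels, raw coefficients averaged
  arithmetically (Fisher-z behind a flag); computed per condition and
  averaged (a pooled concatenation mode exists). Zero-variance pairs are
  skipped and counted; a subject with no valid pair is an error.
* **Centroids**: unweighted mean mm coordinate of the top-10% voxels; group
  comparison by Student's pooled-variance t per axis (Welch behind a flag),
  BH-FDR across the three axes. An axis with zero variance in both groups
  reports NaN t rather than a fabricated value.
* **Brain–behaviour**: all variables z-scored, behaviour regressed on TiFC
  plus covariates by OLS; the TiFC coefficient and its p-value are reported.

## Scenario defaults (the emulated study conditions)

`scenario_config()` encodes the qualitative findings as ground truth:
ONM amplitude offset 1.2 vs OM 0.3 vs YNM 0 (strong upregulation held back in
OM); ONM peak shift +4 mm superior; ONM heterogeneity 0.12 vs 0.20 elsewhere
(more homogeneous ONM patterns, hence higher within-group ISPC); OM
behaviour slope −0.2 with noise 0.08 (negative connectivity–behaviour
coupling); resting-state offsets 0.5 for both older groups; template
amplitude 2 with noise 0.2 so that spatial signal dominates voxel noise the
way ROI-averaged connectivity maps do. Behaviour intercepts (0.55/0.39/0.70)
place mean accuracies near the observed group levels (~0.45 for older
groups, ~0.7 for young). Eight ROIs (four per hemisphere) are simulated; the
ISPC/centroid stage runs on left PrCGsup and behaviour couples to right SMA.

Problem sizes used in the validation suite: 200 subjects per coupling
amplitude for gPPI bias, 200 cohorts for mixed-model recovery, 500
experiments × 2,000 iterations for bootstrap calibration, 100 (shift) and
1,000 (null) cohorts for the centroid statistic, 1,000 replicates for type-I
error of ANOVA and partial correlation, and 20 seeded end-to-end runs for
the scenario pattern.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; a pipeline run derives all stage seeds
from the single config seed, so reruns are byte-identical. Rank-deficient GLM
designs raise an error naming the collinear columns (pivoted QR); the gPPI
solver uses minimum-norm least squares so that the (identifiable)
interaction coefficients are exact even when seed and task regressors are
collinear in noiseless data. Bootstrap with fewer than 100 iterations warns.
Empty ROIs, empty groups, bands outside Nyquist, series shorter than two
low-cutoff cycles, and constant predictors all raise explicit errors.

## Known limitations

The LMM p-values are Wald z-tests (as in lme4), anti-conservative for very
few region levels. The robust LMM mode is a response-clipping approximation
to a full robust REML. The neural-mode gPPI depends on the deconvolution
regularisation constant and attenuates coupling amplitudes; it is provided
for comparison, not as the default. ISPC significance uses subject-level
t-tests and ignores the dependence induced by shared reference subjects.
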