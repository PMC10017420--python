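# Methods

## Problem setting

Intravenous ICG (0.05 mg/kg, a dose low enough to keep the 8-bit NIR sensor
out of saturation even though healthy liver concentrates the dye) produces a
time–fluorescence curve in every pixel of a NIR surgical recording.
Metastatic tissue is supplied by a fast, leaky bolus path: it enhances
early, peaks around 24 s and washes out steeply. Healthy parenchyma
actively takes ICG up: it rises slowly, peaks near 80 s at a higher
intensity, and barely declines within a 90 s window. Benign cysts are
avascular fluid and barely enhance at all. Everything in this package —
feature definitions, classifier protocol, heatmap construction and the
synthetic-data generator — is built around exploiting that contrast within
the first 90 s after injection, sampled at a nominal 30 fps
(2700 samples per trace; the window length is configurable, e.g. 2698
samples for 89.93 s).

## Milestone features

For one ROI trace `F(t)` (mean 8-bit NIR intensity over the tracked
polygon, `t` relative to the window start):

- smoothing: a 1.0 s centred moving average (shrinking windows at the
  edges) is applied before peak finding and slope reads; the centre of mass
  and the value moments use raw samples. The source protocol does not
  specify smoothing; 1 s suppresses sensor noise without displacing the
  broad peaks involved.
- baseline: mean of the first second of the raw trace; used only for the
  half-rise and onset thresholds. Tabulated intensities are raw.
- `Tmax` = earliest time of the smoothed maximum (ties → earliest);
  `Fmax` = that maximum; end intensity = last smoothed sample.
- `T½` = first time the baseline-subtracted smoothed curve reaches half of
  `Fmax − baseline` (linear interpolation between samples); time ratio =
  `T½ / Tmax`.
- upslope = `(Fmax − F_onset) / (Tmax − t_onset)` with onset at 10 % of the
  dynamic range. The onset fraction is a documented constant; the upstream
  definition of upslope is not public, so this is a package decision.
- outflow: `delta10 = F(t* + 10) − F(t*)` and `slope_k = (F(t* + k) −
  F(t*))/k` for k = 10, 20, 60 s, on the smoothed curve. Lesion and benign
  ROIs anchor at their own peak (`t* = Tmax`); healthy ROIs anchor at the
  mapped reference peak — the lesion `Tmax` of the same recording, or the
  mean when several lesion ROIs exist — because healthy curves have no
  early peak of their own. `delta10 ≡ 10·slope10` holds exactly by
  construction. If `t* + k` falls outside the window the feature is
  missing (NaN), never silently zero.
- skew and excess kurtosis: Fisher–Pearson g1 and g2 of the distribution
  of intensity *values* over the window (not of the curve as a density
  over time). The value-distribution reading is what makes a saturating
  curve — most samples near the maximum — come out negatively skewed.
  The excess-kurtosis convention is a package choice; the upstream
  convention is not stated.
- COM = `Σ t·F(t) / Σ F(t)` over raw samples: late COM means retained
  signal, early COM means transit.

## Synthetic angiogram generator

No surgical recordings are distributable, so validation runs on synthetic
data whose *extracted* milestones are calibrated to the published
per-class milestone statistics bundled in `icgdyn.reference`.

**Curve family.** Each tissue class rises as a gamma variate
`F = b + A·(τ/tp)^a · exp(a(1−τ/tp))` (arrival delay d, peak exactly
`b + A` at `d + tp`). After the peak there are two branches:

- *retention* (healthy, rim, cyst): a convex mix of the gamma-variate
  decay and a retained plateau, modelling hepatic ICG concentration;
- *dip–recovery* (lesions): `F = peak − D(1−e^{−τ'/6s}) + U(1−e^{−τ'/45s})`
  — a fast bolus washout over a slow re-accumulation. D and U are solved
  from the 10 s intensity-change and end-intensity targets as a 2×2 linear
  system. A pure single-component curve cannot reproduce the lesion
  pattern (steep −24 g.u. drop within 10 s of the peak, yet an end
  intensity only 17 % below the peak at 90 s); the dip–recovery shape can,
  and its calibrated curve also lands close to the published 20 s and 60 s
  slopes without targeting them.

**Calibration** is closed-form: shape from the half-rise target,
retention (or D, U) from the washout targets; a two-step deterministic
fixed-point nudge compensates the ~0.5 s early shift that 1 s smoothing
induces on the kinked lesion peak, so the *extracted* `Tmax` matches the
target. The result is verified by running the noise-free curve through
the package's own milestone extractor (2 % tolerance) — calibration fails
loudly rather than drifting.

**Cohort variability** is sampled in *milestone space*: each lesion draws
(`Tmax`, `Fmax`, time ratio, washout fraction, 10 s drop) from lognormal
distributions whose means and CVs come from the reference table, truncated
to physical ranges (peak intensity ≤ 250 g.u., matching the
saturation-avoiding dose) with the lognormal location re-solved under
truncation so the truncated mean still equals the target. Sampling
milestones (rather than jittering kinetic parameters) keeps recovered
milestone *means* unbiased; nonlinear parameter-to-milestone maps would
shift them. The cohort mirrors the study design: 132 lesion ROIs over 24
patients (one lesion each), one healthy reference ROI per patient, and 6
ROIs on a single benign cyst. ROIs of one lesion share the solved kinetic
shape and differ by a mean-one lognormal amplitude factor (CV 0.12):
within one video, timing and washout are lesion-level properties, while
enhancement varies spatially. (Solving a separate shape per ROI is also
numerically ill-conditioned for near-total-retention curves, where tiny
milestone jitter produces wild shape swings no real lesion shows.)

Cysts use healthy-like late timing at ~22 % of healthy amplitude with
near-total retention: an avascular cyst's apparent signal passively tracks
the surrounding parenchyma, scaled down — which is also why cyst regions
show no margination in rendered scenes.

**Scenes.** `render_sequence` draws a padded world (healthy background,
circular lesion, rim annulus with boosted retained signal, optional cyst,
background border), a smooth per-pixel amplitude field, a static
white-light texture with vessel-like dark spots (strong corners for
tracking), and per-frame motion: a global affine random walk
(translation + small rotation) plus a single-frequency sinusoidal
respiration displacement with a smooth spatial envelope. Both channels
share the motion; NIR frames get Gaussian sensor noise (SD 2 g.u.),
clipping at 255 and 8-bit quantization. The full ground truth (class map,
amplitude field, per-frame displacement, kinetics) is returned alongside.

**Microscopy.** Sections carry lesion/healthy region means of 2.46 and
507.43 (arbitrary units — the upstream intensity scale is not public) with
unit-mean lognormal pixel texture; the stained rendering equals the
unstained rendering divided by the attenuation factor (default 6.5) before
texture, so the attenuation ratio is recovered exactly.

**What the generator does not model:** photorealistic anatomy, specular
highlights and instrument occlusion, pharmacokinetic coupling between
tissues, breathing irregularity, rolling-shutter or compression artefacts,
cirrhotic parenchyma. Passing tests therefore demonstrate correctness of
the *pipeline* under controlled conditions, not clinical performance.
Known fidelity gaps: the healthy-class time ratio comes out ≈ 0.6–0.7
(the published 0.127 implies a fast early component that no unimodal
single-bolus family peaking at 83 s can reproduce), healthy mapped-peak
slope10 is ≈ +1 rather than +3.7, and the milestone spread of the time
ratio is narrower than the published SD.

## Classifier protocol

Stratified 80:20 split (optionally grouped by patient), then a grid search
over decision-tree hyperparameters (depth 1–10, min leaf {1, 2, 5, 10,
20}, gini/entropy) scored by 10-fold cross-validated accuracy; ties prefer
shallower trees, then larger leaves. Fold membership is the hash of
`roi_id` and the seed — reproducible and row-order independent. CART
breaks exact impurity ties by a random feature permutation, so the search
also tries three tie-break states per configuration under the same
accuracy criterion; with few benign ROIs many features separate the
training set exactly, and this lets cross-validation reject
narrow-margin tie-break choices. Imputation happens strictly within the
training side of each fold: outflow features missing because the peak sits
within 10/20/60 s of the window end impute to 0 (no observable washout);
everything else imputes to the training median. Reports give the
confusion matrix, overall accuracy, PPV for the lesion class versus rest,
and per-class TPR/FNR, percentages to one decimal.

## Stabilization and 2D maps

Frames are decimated to 7 fps by nearest-index selection (8-bit values
survive untouched). Shi–Tomasi corners are detected once on the reference
frame (the middle retained frame, minimizing warp extrapolation) and
matched into every retained frame by normalized cross-correlation of
13×13 patches within an 8 px window centred on the previous frame's
prediction; sub-pixel refinement by parabolic interpolation of the
correlation peak (skipped for integer-perfect matches, where it would only
add bias); deterministic trimmed least-squares consensus against a
similarity transform (2 px residual cut) rejects outliers. Each frame is
matched *directly* to the reference rather than chained frame-to-frame:
composition accumulates the sub-pixel bias of discrete correlation peaks
(~2 px drift over 90 s in testing), while direct matching holds the
residual near 0.5 px RMS against the generator's ground-truth motion.

The matched landmarks drive a standard thin-plate-spline warp
(`U(r) = r² log r`, affine part + kernel weights, regularization λ;
λ = 0 interpolates exactly and reproduces affine motion exactly; the
default λ = 1 damps landmark noise). NIR frames are resampled through the
warp (bilinear); pixels leaving the field of view in any frame are masked
invalid and render as the grey border.

Per-pixel maps: COM of each valid pixel's curve; outflow slope between the
pixel's own smoothed peak and peak + 10 s (missing when the peak is within
10 s of the window end — whether the study used per-pixel or global peaks
is not stated; per-pixel chosen). Clustering: k-means (k = 3 by default —
lesion / rim / background; the study names neither algorithm nor k) on
z-scored per-pixel descriptors, either the optimal piecewise-constant
segment levels (default 5 segments, exact O(kT²) dynamic programming,
curves decimated to ≤ 150 samples) or the (COM, slope) pair. Labels are
relabelled by ascending cluster-mean COM for determinism. Rendering: COM
on viridis (late = yellow), slope on a red–blue diverging palette centred
at zero (negative = red), cluster labels categorical, invalid pixels grey.

## Statistics

Shapiro–Wilk for normality screening (3 ≤ n ≤ 5000), two-sided
Mann–Whitney U for group comparison (exact p for small tie-free samples,
tie-corrected normal approximation otherwise), α = 0.05, no
multiple-testing correction (raw p per row, as the reference table
reports), sample SDs with n−1.

## Numerical conventions and degenerate inputs

Coordinates are 0-based (row, col); time 0 at the first frame; the
analysis window is half-open [0, 90 s). Flat traces raise
`UndefinedFeatureError` for half-rise/upslope/moments (NaN inside
`compute_features`); all-invalid tracking raises `TrackingError`; collinear
landmarks raise `DegenerateConfigurationError`; landmark failures beyond a
configurable gap abort stabilization. Identical seeds give bit-identical
scenes and identical cluster maps.

## Problem sizes

The bundled tests validate on reduced scenes (≈ 80×100 px, 10 fps, 25–40 s)
and the full 162-ROI cohort at 30 fps/90 s; the acceptance script uses 200
traces per milestone target and the full cohort. These sizes were chosen
so the complete validation runs comfortably on a laptop-class single core
while exercising every code path at the study's native sampling rate.
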