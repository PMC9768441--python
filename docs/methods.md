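# Methods

`mocolab` compares strategies for correcting head-motion effects in
block-design task fMRI. Because its purpose is methodological — which
correction model preserves task activation best under which motion regime —
every stage operates on synthetic phantoms whose activation, motion, and
noise are known exactly. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic evaluation does and
does not show about real data.

## Motion model and metrics

Head position at volume *i* is a rigid transform with six parameters
(translations x, y, z in mm; intrinsic pitch, yaw, roll rotations about
volume-center axes in radians, composed Rz·Ry·Rx). Motion comes in two
regimes: a gradual random-walk drift, and transient spikes — a single-volume
displacement that returns to the drift path at the next volume. A transient
spike therefore produces **two** large frame-to-frame displacements (the
displaced frame and the recoil frame); the generator records this affected
frame pair as its ground-truth outlier set.

**Framewise displacement (FD).** The L1 norm of the backward differences of
the six parameters, with rotational differences converted to mm of arc on a
sphere of radius 50 mm (the standard head-size approximation; configurable).
FD(0) = 0. Frames with FD strictly above 0.5 mm are motion outliers; the
strict inequality means a frame exactly at threshold is not flagged.

From FD and the outlier mask we report meanFD (all frames), meanFD′
(non-outlier frames), and meanFD″ (outlier frames only); an empty subset's
mean is a null sentinel. meanFD always lies between the two subset means.

**DVARS.** The spatial root-mean-square, over the brain mask, of the
temporal backward difference of image intensity, divided by the median
in-mask intensity of the temporal mean image and scaled to % ΔBOLD.
DVARS(0) = 0. Outliers are frames strictly above the per-run boxplot
threshold P75 + 1.5·IQR (percentiles by linear interpolation between order
statistics). The normalization affects reporting only: the boxplot rule is
scale-invariant.

**Motion-explained variance.** For a motion-regressor set X with P columns
and the spatial-mean BOLD signal b over N volumes, we report

    R²_adj = 1 − (N−1)/(N−P−1) · SS_res / SS_tot,

with an explicit intercept that is never counted in P and SS_tot about the
mean of b. `adjusted=False` gives the plain R², which is monotone under
nested regressor sets; the adjusted value need not be, which is exactly the
over-parameterization signature the 6-vs-24-parameter comparison probes.

## Realignment

Parameters are estimated per volume against the first volume by minimizing
the mean squared intensity difference after rigid resampling, with a light
Gaussian presmoothing (σ = 1 voxel), a 2-voxel border excluded from the
cost (constant padding must not vote), Powell refinement warm-started from
the previous volume's estimate, and a coarse ±1-voxel translation grid as a
fallback for poor fits.

Two numerical choices deserve emphasis:

- **Cubic resampling inside the cost only.** Trilinear interpolation
  attenuates high-frequency image content by an amount that depends on the
  fractional-voxel offset. For small rotations the resulting error pattern
  is as large as the misalignment signal itself and biases the cost minimum
  toward zero rotation. The similarity cost therefore resamples with cubic
  splines; all *data* resampling (the forward motion model and the
  realignment output) remains trilinear.
- **Rotation identifiability.** The precision of rotation estimates is
  limited by the number of informative brain voxels: on a desk-scale grid
  (~3 k brain voxels) at 1% thermal noise the floor is roughly 0.005 rad,
  scaling as 1/√n_voxels. Parameter-recovery tests therefore run at 0.3%
  noise on a 24³ grid, which matches the information content of a
  full-resolution acquisition (~2×10⁵ brain voxels) at ordinary noise
  levels. Translation recovery is insensitive to this choice.

The 24-parameter expansion is the Friston-style `[MP, MP², ΔMP, (ΔMP)²]`
(backward differences, row 0 of the Δ columns zero); the published phrase
"squares and temporal derivatives" underdetermines the recipe, and this is
the standard set producing exactly 24 columns. Its first six columns are
the raw parameters, which the nested-R² tests rely on.

## Correction models

Nine models per run, all operating on the realigned series:

| id | nuisance regressors | outlier handling |
|----|--------------------|------------------|
| realign_only | none | none |
| mp6 / mp24 | 6 / 24 MPs | none |
| mp6_fd / mp24_fd | MPs + one-hot scrub columns | FD > 0.5 mm |
| mp6_dvars / mp24_dvars | MPs + one-hot scrub columns | DVARS boxplot |
| mp6_interp / mp24_interp | 6 / 24 MPs | linear interpolation of FD outliers |

Nuisance regression is ordinary least squares per voxel with one shared
pseudoinverse, an always-present intercept, and the voxel temporal mean
added back so cleaned data stay on the original intensity scale. Constant
(including all-zero) confound columns are dropped rather than erroring, so a
motion-free run degrades to a near-no-op; genuinely collinear columns (e.g.
duplicated scrub regressors) raise an error naming the offending columns.
Because scrub columns are one-hot, the residual at a scrubbed volume is
exactly the voxel mean — an algebraic identity the tests verify to 1e-8.

Interpolation replaces each flagged volume with the linear interpolant in
time between the nearest non-flagged neighbors (runs of flags become ramps;
leading/trailing flags copy the nearest good volume; a nearest-neighbor
interpolant is available and recorded in provenance). For the interp models
the order is MP regression first, interpolation second, as the final
preprocessing step; outliers for interpolation are always FD-detected. The
operation is idempotent for a fixed mask.

The two-step structure (clean first, then GLM) mirrors common practice even
though joint estimation is statistically cleaner; it also means the GLM's
residual degrees of freedom do not account for scrubbed frames, a known
property of two-step scrubbing shared by the pipelines this package
emulates.

## Task GLM

Task regressors are unit boxcars sampled on a 16× oversampled grid,
convolved with the canonical double-gamma HRF (response peak 6 s, undershoot
peak 16 s, unit dispersions, undershoot ratio 1/6, 32 s support, kernel
scaled to peak 1) and decimated to volume times. Drift is modeled by DCT-II
columns for all periods at or above the high-pass cutoff (k = 1 …
⌊2·T·TR/cutoff⌋); the same subspace is used by the `highpass` filter, so
filtering commutes with fitting. Spatial smoothing is an isotropic Gaussian
(default FWHM 3 mm) renormalized at the mask edge.

Voxelwise OLS gives β, residual variance SS_res/(T−rank X), and contrast
t-scores t = c′β/√(σ̂²c′(X′X)⁻¹c), converted to Z by probit-matching the
t CDF at the model's degrees of freedom and clipped at |Z| = 38.
Zero-variance voxels get Z = 0.

Family-wise control replaces random-field theory (whose smoothness
estimation is out of scope) with a Bonferroni voxel threshold over the mask
plus a minimum cluster extent on 26-connected components — conservative by
construction. A circular-shift maximum-statistic permutation null
(`permutation_null_max_z`) is provided as a less conservative alternative;
cluster lists are sorted by peak Z, ties by size then lexicographic peak
coordinate, so outputs are deterministic.

Quality metrics per thresholded map: Z-max (highest surviving Z) and Z-mean.
"Mean Z of all significant clusters" is ambiguous between averaging voxels
and averaging cluster means; both are implemented, and the voxel-weighted
union is the default recorded in provenance.

## Synthetic phantom

The phantom is an anisotropic ellipsoid "brain" (semi-axes 0.40/0.34/0.29 of
the grid — heads are not spheres, and the anisotropy is what makes rotations
identifiable to intensity-based realignment) with a smooth sigmoid edge,
10% smooth random texture, baseline 1000, background ≈ 0. Voxel time
series are

    baseline(x)·(1 + Σ_ROI amp·s(t) + drift(t)) + noise,

where s(t) is the HRF-convolved boxcar of the ROI's condition normalized to
peak 1 (so `amplitude_pct` is peak % signal change), drift a slow sinusoid
(default 0.5% at 128 s period, random phase), and noise Gaussian with
default sd 1% of baseline. Noise is given a short spatial correlation
(Gaussian σ = 0.75 voxel, rescaled to the nominal sd): real EPI noise is
spatially correlated, and perfectly white noise interacts with trilinear
resampling to produce a frame-position-dependent variance modulation that
contaminates DVARS with a spurious gradient over the run.

Two block-design presets mirror a visual-motion study at TR = 1 s: a
localizer (192 volumes; ten 18 s blocks of fixation/static/moving after a
12 s lead-in; conditions static and moving; contrast moving − static;
high-pass 24 s) and biological-motion runs (507 volumes; twelve 40 s blocks
from conditions global/local/scrambled, variants a and b carrying 5/4/3 and
4/5/3 blocks so two runs total 9/9/6; balanced contrast; high-pass 80 s).
Activation sits in a compact sphere standing in for the motion-sensitive
area hMT+/V5.

`apply_motion` resamples each volume under its rigid transform (trilinear,
edges padded with the phantom's own background level) and multiplies
spike-displaced volumes by a global intensity factor (default 4%) emulating
the spin-history/intensity disruption that accompanies abrupt movement —
this is what gives image-based (DVARS) detection a target and what makes
outliers genuinely destructive, the regime outlier-correction methods exist
for.

What the phantom does **not** emulate: k-space/slice-timing effects,
susceptibility distortion and its motion interaction, physiological
(cardiac/respiratory) noise, anatomical variability across subjects, and
spatially structured motion artifacts (our spike artifact is a global
scale). Consequently the evaluation shows how the correction models behave
when outliers are frame-localized intensity disruptions on top of rigid
motion; it cannot show, for example, whether DVARS or FD detection is more
sensitive to slice-wise artifacts.

## Evaluation harness

The study layout is two cohorts (17 and 14 subjects, mirroring a
patient/control design) × three runs (localizer + two BM variants) × nine
models, on a reduced 16³ grid of 2 mm voxels chosen so the full 93-run sweep
takes a few minutes on one CPU. Motion defaults: drift 0.02 mm per step,
one transient 1 mm spike per 100 volumes with the 4% intensity artifact.
The harness uses the generator's ground-truth traces (inverting the known
transforms) rather than re-estimating them: realignment accuracy is
validated separately, and fixing the traces isolates the correction-strategy
comparison from registration error; `motion_params="estimated"` switches to
full estimation.

Per run the harness emits the nine quality-metric records plus the motion
characterization (three FD means, spike count, and R²_adj for the eight
regressor sets {6, 24} × {plain, FD-scrub, DVARS-scrub, interp}; the interp
variant regresses the MPs against the interpolated mean signal, since
interpolation adds no columns). Metrics are averaged over a subject's runs.
Group and model comparisons use paired sign-flip permutation tests on the
subject-level metrics — exhaustive over all 2ⁿ sign patterns when feasible,
Monte Carlo with the add-one estimator otherwise. Mixed-design ANOVAs with
an age covariate would be the parametric analogue, but synthetic cohorts
have no age and the permutation test is assumption-light and exactly
testable.

The machine-readable report records, per cohort, the model ranking by mean
Z-max, the median-Z-max comparison of each outlier-corrected model against
its MP-only reference, and the 6-vs-24 family comparison with its
per-subject frequency.

**A structural caveat the comparison itself reveals.** With transient
spikes, the ΔMP and (ΔMP)² columns of the 24-parameter set are nearly
one-hot at the spike and recoil frames (the spike step dwarfs the drift
step), so the 24-MP model already "self-scrubs" spike-frame artifacts.
Adding explicit scrub columns to it then removes only task signal at those
frames, and the 24-MP scrub models sit slightly *below* plain 24-MP on
median Z-max — whereas for the 6-MP family all three outlier corrections
help clearly, and interpolation helps in both families. The report states
these comparisons as computed; the package does not force them.

## Determinism and sizes

Every stochastic stage is driven by explicit integer seeds
(`numpy.random.default_rng`); the full comparison is bit-stable given its
config seed, and per-subject seeds are derived arithmetically from it. The
default test suite runs in about 5 minutes on one CPU; the acceptance script
(full comparison plus the standalone validations) in about 4. Problem sizes
used by the tests — 16³–24³ grids, 6–192 volume runs, 10–100 seed
repetitions — were chosen as the smallest sizes at which each property is
cleanly measurable.
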