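# Methods

This note documents the models, estimators, parameter defaults and
numerical conventions implemented in `alphashift`, and what the
synthetic test bed does and does not establish.

## Spectral estimation

Segments are re-referenced to the common average, cut into 1-s epochs
with 90% overlap, demeaned per epoch and channel, multiplied by a
**periodic** Hann taper (`scipy.signal.windows.hann(L, sym=False)`),
zero-padded to `pad_factor × L` samples (default `pad_factor = 2`), and
Fourier transformed; squared moduli are averaged over epochs. Power at
the integer frequencies 2…20 Hz is extracted and normalized per channel
by its sum over those 19 bins ("relative power"). Conventions worth
making explicit:

* **Epoch step rounding.** At 256 Hz a 90% overlap implies a fractional
  25.6-sample step; the step is rounded to 26 samples (89.84% effective
  overlap), giving a deterministic 188 epochs for a 20-s segment.
* **Zero-padding.** With 1-s epochs and `pad_factor = 2` the native
  resolution is 0.5 Hz and the integer-Hz bins are exact FFT bins. The
  code refuses frequency/padding combinations for which the requested
  integer frequencies fall between bins.
* **Normalization denominator** is the sum over the extracted 2–20 Hz
  bins only, not the full Nyquist range. All relative-power rows
  therefore sum to exactly 1, and any per-channel gain cancels
  (scale invariance is property-tested).
* **Hann leakage.** A bin-centered sinusoid concentrates exactly 2/3 of
  its extracted power at the peak bin and 1/6 at each ±1 Hz neighbour
  (closed form for the Hann taper, pinned in the tests). Statements
  about near-total spectral concentration hold only for the direct
  unwindowed DFT of a pure tone, which the tests use as the oracle.

The **alpha-power shift** is the binary log of the ratio of mean
relative power in the inclusive low-alpha band {6,7,8,9} Hz over the
inclusive high-alpha band {10,11} Hz. The log is used throughout (it
removed variance heterogeneity between groups in grand-average
testing and makes the ratio symmetric around 0). The *global* shift is
computed from the channel-averaged spectrum (averaging first, then the
ratio); the mean of the per-channel log ratios is exposed separately as
`mean_channel_log2_shift` since the two summaries differ in general.
The individual alpha frequency (IAF) is the argmax of the
channel-averaged spectrum in 6–13 Hz, ties broken toward the lower
frequency.

## Synthetic cohort generator

Each subject's segment is the sum of a topographic narrowband alpha
component and 1/f background noise, at 256 Hz over the 19-channel
10–20 montage, 20 s per segment.

* **Alpha component.** Random-phase spectral synthesis in
  `peak_freq ± bandwidth/2` (default bandwidth 2 Hz), one *independent*
  realization per channel, each normalized to unit RMS and scaled by
  `amplitude × gain(channel)`. Inter-channel alpha coherence is
  deliberately not modeled: with a single shared source, the
  common-average reference folds the source into every channel and
  per-channel amplitude topography becomes unidentifiable from the
  shift statistic.
* **Topographic gain.** `gain = s + (1 − s) · g0(y)` where
  `g0` decays linearly from 1 at the most posterior electrode to 0 at
  the most anterior and `s = anterior_spread ∈ [0, 1]`. `s = 1` gives a
  flat topography; occipital amplitude is independent of `s`.
* **Background.** White Gaussian noise of RMS `white_sd` (default 1.0,
  i.e. half the default alpha RMS of 2.0 at the occiput), spectrally
  shaped to a 1/f^a power law with exponent `a = 1` by default.
* **Montage.** Idealized spherical 10–20 positions (vertex ring at 36°,
  circumferential ring at 72°, parasagittal sites as great-circle
  midpoints), azimuthal-equidistant projection, head radius 100 mm.
* **Cohort defaults** mirror a 39/25/38 three-group clinical cohort:
  healthy subjects (alpha peak 10.5 Hz, spread 0.15, age 30 ± 9,
  49% female), good seizure control (10 Hz, spread 0.25, age 33 ± 12,
  60% female, AED load 1.4 ± 0.9, 40% focal syndrome), poor seizure
  control (8 Hz, spread 0.60, age 38 ± 14, 50% female, AED load
  1.5 ± 0.8, 71% focal). Per-subject peak frequency jitters around the
  group peak with SD 0.5 Hz and amplitude with a lognormal CV of 0.3.
* **Seizure counts** are negative-binomial per control level
  (overdispersed, so the rank-correlation control analysis is
  exercised); good-control draws are clipped below four and
  poor-control counts are four plus the draw, so the dichotomization
  rule (poor control ⇔ ≥ 4 seizures/12 months) holds by construction.

Everything derives from a single integer seed via spawned
`SeedSequence`s; identical designs give byte-identical segments and
tables.

**What the generator does not emulate:** interictal discharges,
spike-wave activity, eye-blink/muscle artifacts, drowsiness (the
target recordings are expert-selected to be free of these); volume
conduction and inter-channel coherence; realistic spectral shapes
beyond a single alpha bump on a 1/f background; circadian or
medication-specific effects. Passing tests therefore establish the
*statistical machinery* — calibration, recovery, localization — under
a clean generative model, not performance on real EEG.

## Grand-average statistics

ANCOVAs use Type III sums of squares with sum-to-zero factor coding on
an ordinary-least-squares substrate; each effect's F compares the full
model against the model with that effect's column block removed.
η² is reported classically as SS_effect / SS_total. The one-way model
(three groups + age + gender) has error df N − 5 (97 for 102
subjects); the factorial model (two mains, interaction, age, gender,
AED load) reports a single consistent error df of N − 7 (56 for 63
patients) for all three effects, as they come from one full model.

Planned contrasts are **plain pooled two-sample t-tests on the log2
shift** (df = n_a + n_b − 2), not covariate-adjusted contrasts; the
analysis this package operationalizes reports contrast dfs of n − 2
(100 and 61), which identifies the unadjusted form. Bonferroni
correction is applied within each model's family of contrasts.
Hedge's g uses the small-sample correction J = 1 − 3/(4N − 9) and a
percentile bootstrap over subjects (5000 resamples by default) for its
CI. Raw samples and their summary statistics give identical t, df, p
and g.

Assumption checks: Levene's test on absolute deviations from group
*means* (the mean-centered variant is mildly liberal in very small
groups and asymptotically calibrated — its type-I simulation uses
60/group); slope homogeneity as the F-test of the group × covariate
interaction block; Shapiro–Wilk on residuals. A guard returns F = 0
for (near-)perfect model fits where the F statistic is formally 0/0.
The seizure-frequency association uses Spearman's rho with a seeded
permutation p (10 000 shuffles, two-sided) rather than the asymptotic
approximation, because of small n and ties from integer counts.

## Scalp maps and permutation inference

Per-channel shifts are linearly interpolated on the Delaunay
triangulation of the electrode positions onto a **32 × 32-node** grid
spanning the bounding square of the head circle (the grid is read as
32 × 32 nodes, since a 32-mm spacing over a ~200-mm head would give ~7
nodes and no smooth topography). Nodes outside the convex hull are
masked, never extrapolated. Smoothing is an isotropic Gaussian with
σ = 8 mm, mask-normalized so constants survive at the boundary;
σ = 0 is the identity.

Node-wise statistics use the Aspin–Welch unequal-variance contrast t in
a linear model with covariates: residual variance is estimated per
variance group on df_g = n_g − tr(H_gg) (leverage-corrected), the
contrast variance is the per-group sandwich sum, and
Welch–Satterthwaite combines the contributions into an effective df.
With a single variance group this reduces exactly to the pooled OLS t;
with two groups and no covariates it reduces exactly to the classical
Welch test (both reductions are oracle-tested).

Freedman–Lane permutation: fit the nuisance-only model, permute its
residuals, add back the nuisance fit, recompute the contrast t at every
node. `p_uncorrected = (1 + #{perm t ≥ observed}) / (1 + n_perm)`
(the +1/+1 is the observed labelling; the smallest achievable p is
1/(1 + n_perm) and p = 0 is never reported), and `p_fwe` uses the
permutation distribution of the maximum statistic over unmasked nodes.
Inference is one-sided in the contrast direction by default (contrasts
are directional); a two-sided |t| option exists. Permutations are drawn
uniformly without uniqueness enforcement; with ≤ 8 subjects, or
whenever `n_perm` reaches the number of distinct permutations, the full
permutation group (identity excluded) is enumerated instead — beyond
8 subjects exhaustive enumeration (9! ≈ 3.6 × 10⁵, 10! ≈ 3.6 × 10⁶
relabelings) is disproportionate and Monte-Carlo sampling is used.
Effect-size maps compute node-wise Hedge's g with subject-level (never
node-level) bootstrap CIs; zero-variance nodes are flagged NaN. Peak
localization reports the maximum statistic, its Welch df, and the
Euclidean-nearest electrode (ties broken alphabetically).

## Classification

Features are the 19 per-channel log2 shifts (a global scalar option
exists). The discriminant is Fisher's w = Σ⁻¹(μ₁ − μ₀) from the pooled
within-class covariance with a ridge of `1e-6 × trace/dim` on the
diagonal for numerical stability, thresholded at the equal-prior
midpoint (classes are imbalanced and no prior policy is imposed).
Performance is estimated with repeated stratified k-fold CV (defaults
k = 10, 100 repeats): per repeat, sensitivity/specificity from pooled
out-of-fold predictions and AUC from pooled out-of-fold scores
(rank-based); summaries are mean ± SD over repeats with a normal
approximation 95% CI (mean ± 1.96 SD). Repetition is what gives the SD
— a single k-fold run has none. The AUC z-test uses the rank-sum normal
approximation with tie and continuity correction, which tracks the
exact permutation distribution closely from ~8 subjects per class.

## Problem sizes used in validation

Simulation-based checks use: 2000 replicates for the scalar type-I
calibrations (ANCOVA F at 39/25/38, Levene at 60/group, AUC z at
25/38); 500 replicates × 500 permutations at 8/8 subjects for
family-wise-error calibration of the Freedman–Lane max-statistic
procedure; 100 replicate cohorts at 25/38 for effect-size recovery;
and 18/18 cohorts for topographic localization. These sizes give
binomial 95% CIs tight enough to detect meaningful miscalibration
while keeping the full suite to a few minutes on one CPU.

## Known limitations

* The EDF writer is minimal (16-bit, 1-s records, integer sampling
  rates and whole-second durations) — sufficient for this package's
  segments, not a general EDF+ implementation.
* Common-average referencing makes channel statistics reference-
  dependent; topographic claims are about the re-referenced data, as
  is standard.
* The generator's spectral shape is a single alpha bump on 1/f noise;
  absolute effect sizes on synthetic cohorts are by construction and
  do not predict clinical effect sizes.
* Non-256-Hz recordings are rejected rather than resampled; resampling
  is out of scope.
* Cluster-extent and threshold-free cluster enhancement inference,
  spline/spherical-harmonic interpolation, and source-space analysis
  are not implemented.
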