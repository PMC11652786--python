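# Methods

`nirsfc` implements a task-free functional-connectivity analysis for
neonatal continuous-wave fNIRS: automated signal-quality screening and
motion-free segmentation, optical preprocessing to hemoglobin
concentration changes, channel-pair Fisher-z connectivity, and mixed-model
inference on gestational and postnatal age. A synthetic-data generator
with full ground truth makes every stage verifiable at desk scale. This
note records the models, the numerical choices, and what the synthetic
validation does and does not show.

## Montage model

The instrument couples 8 LED sources (760/850 nm) and 8 detectors into 20
channels, 10 per hemisphere. No optode coordinates enter the analysis:
every downstream computation depends only on each channel's hemisphere
label and its source-detector separation. The bundled default layout
assigns separations mirrored across hemispheres with mean 35.7 mm and SD
9.5 mm over the 20 channels, matching the acquisition geometry the
analysis is designed for; the table is replaceable by any 20-row layout
with a 10/10 hemisphere split. Channel separations are rescaled linearly
by the subject's head circumference relative to a 350 mm reference; a
missing circumference leaves the reference distances in place (with a
logged warning) rather than excluding the subject.

Channel pairs are classified as `left_intra` (45), `right_intra` (45) or
`inter` (100); the three classes partition the 190 unordered pairs.

## Quality control

**Cardiac presence.** A channel is kept only if both wavelengths show a
clear cardiac spectral peak. The statistic whitens the Welch spectrum with
a log-log linear background fit over 0.5–4.5 Hz, then takes the whitened
peak inside the cardiac band divided by the median whitened power outside
the peak bin; channels with ratio ≥ 3 are retained. The background fit is
essential: physiological fNIRS backgrounds are 1/f-like, and a raw
peak-to-median ratio flags a 1/f spectrum as "cardiac" in roughly a third
of runs, while the whitened statistic stays below 3 in ≥ 99% of white,
1/f and 1/f² null simulations and exceeds 300 for a genuine cardiac
sinusoid at SNR 10.

**SCI and PSP.** Both wavelength series are band-passed to the cardiac
band (60–210 bpm → 1.0–3.5 Hz) once over the whole recording, then cut
into 5-s windows on a 1-s hop (5-s windows, 4-s overlap; the final partial
window is discarded; sample indices by rounding, since 5 s is a
non-integer number of samples at 10.17 Hz). Within each window both
series are standardized; the scalp coupling index (SCI) is their zero-lag
Pearson correlation, and the peak spectral power (PSP) is the maximum of
the sum-normalized power spectrum of their cross-correlation inside the
cardiac band. On this normalization a coherent cardiac pair yields PSP of
order 0.1–1 and the default threshold is 0.03, with SCI ≥ 0.1.

**Windows to samples to segments.** A window is good when at least 75% of
retained channels pass both thresholds (the montage-wide fraction rule
makes the verdict robust to a single bad channel while still gating on
montage-wide motion). A sample is good only if every window covering it
is good. Interior bad runs strictly shorter than 2 s are bridged (edge
runs never are — a bad stretch at the recording boundary is not "brief
motion between clean data"); good runs of at least 50 s become
motion-free segments. A dataset is excluded when no channel passes
cardiac screening, when no segment survives, or when the total surviving
time is below 2.5 min. The surviving-time proportion (percent, rounded)
reproduces the per-subject accounting of the reference cohort table.

## Preprocessing

Per segment, in order:

1. **Optical density**: ΔOD = −ln(I / mean(I)) per channel and wavelength.
2. **Wavelet despiking**: Daubechies-2 decomposition to level
   max(4, ⌊log₂ n⌋ − 4); within each detail level, coefficients outside
   [Q1 − 0.6·IQR, Q3 + 0.6·IQR] are zeroed. The rule is applied only to
   detail levels whose pass-band lies above the analysis band's upper
   corner (0.08 Hz). Motion spikes are sub-2-s events and live entirely at
   those fine scales; at the coarse levels the same bounds would clip the
   largest ~14% of coefficients of the ordinary hemodynamic fluctuations
   — about half their energy for Gaussian-like signals — and measurably
   shrink the very correlations the pipeline estimates (r = 0.5 → ≈ 0.27
   in simulation). With the band protected, a 0.5-s spike of 10 SD is
   reduced by ~86% while a clean in-band sinusoid changes by < 1% RMS.
3. **Modified Beer–Lambert inversion**: per channel the 2×2 system
   ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·PPF(λ) is solved for
   (ΔHbO, ΔHbR) in µM, with ε in cm⁻¹µM⁻¹ (bundled standard compilation:
   760 nm — HbO 586, HbR 1548.52; 850 nm — HbO 1058, HbR 691.32, in
   cm⁻¹/M), d the head-scaled separation in cm and the neonatal partial
   pathlength factors 0.1063 (760 nm) and 0.0845 (850 nm) applied as
   dimensionless multipliers of d. The absolute concentration scale
   cancels in the later per-segment normalization, so only consistency of
   the table matters; the synthetic forward model uses the same one, and
   inversion∘forward is the identity to 1e-9.
4. **Band-pass 0.01–0.08 Hz**, zero-phase Butterworth order 3
   (forward-backward, reflected padding). This band is extremely narrow
   relative to the 10.17 Hz rate; the filter rings for ~1/low ≈ 100 s from
   any edge discontinuity, and out-of-band components that dominate the
   raw signal (cardiac ≈ 50× the in-band signal in concentration units,
   slow drift) leak through the reflection edges badly enough to corrupt
   connectivity. Three linear guards, identical across channels, run
   first: a least-squares Legendre detrend of order ≈ 2·T·low (removes
   drift with no impulse response to ring), a gentle order-5 low-pass at
   4× the upper corner (removes fast physiology with short settling), and
   a 10-s cosine edge taper (removes the low-pass's own edge transient).
   Measured leakage of a full-amplitude cardiac or drift component into
   the band is ~1e-4 of its amplitude; passband gain is ≥ 0.91
   (0.987 at 0.04 Hz on a 600-s segment).
5. **HbT = HbO + HbR**, then per-segment **normalization** (mean 0, SD 1,
   n−1 denominator) of each analyzed species; channels with zero segment
   variance are flagged invalid rather than propagating NaN.
6. **Concatenation and resampling** of the normalized segments to 4 Hz by
   polyphase filtering (400/1017 rational ratio); segment-start indices
   are remapped and logged. Segments shorter than 1/low = 100 s cannot
   resolve the high-pass corner; this is flagged in the log but the
   filter is applied as configured.

Each stage appends a provenance record; the stage order is a module
constant and is asserted in tests. HbO and HbR are carried through the
same chain in their own normalized streams for the species-specific
analyses.

## Connectivity and group statistics

Per subject, Pearson correlations between all valid channel pairs of the
concatenated 4 Hz series (≥ 150 s required) are Fisher z-transformed with
|r| clamped at 1 − 1e-7. The group map applies a one-sample two-sided
t-test of z against zero per pair (direction read from the sign of t),
restricted to pairs observed in ≥ 10 subjects, with Benjamini–Hochberg
FDR at q = 0.05 across the tested pairs.

## Age models

Per pair: z ~ 1 + GA + PNA with a random intercept for sex, one
observation per subject (a subject intercept is unidentifiable here);
BH-FDR across pairs separately per covariate. Hemisphere-wide: (subject,
pair) observations per pair class, z ~ 1 + GA + PNA with random
intercepts for subject and sex. Since sex is constant within subject, the
crossed specification is exactly a nested one, and it is fitted as
statsmodels MixedLM with `groups=sex` and subject dummies as a variance
component — numerically identical to the one-group crossed formulation
and about 3× faster. REML by default (switchable), covariates on natural
scales (weeks, hours; centering available), Bonferroni across the three
class models at α = 0.05/3. Subjects with more than half their channels
pruned are excluded from the hemispheric models; subjects missing GA or
PNA are dropped listwise everywhere. Degenerate inputs (constant z,
collinear covariates, non-convergence) yield flagged results excluded
from the FDR family, never exceptions.

## Synthetic data generator

The generator emulates the statistical structure this analysis assumes,
with two fidelity tiers.

**Connectivity tier** (`simulate_latent`): multichannel series synthesized
in the frequency domain on a brick-wall support just inside 0.01–0.08 Hz.
With `exact_correlation` (default) the columns are whitened against the
covariance of their band-pass-filtered version, so the sample correlation
of the band-passed series equals the target matrix to numerical
precision; downstream estimates then deviate from truth only through
despiking and resampling, not through spectral sampling noise — with only
~2·0.07·T effective degrees of freedom in the band, in-expectation
imposition would leave sd(r̂) ≈ 0.11 at 600 s, swamping any pipeline
effect one wants to measure. The in-expectation mode (exact off) provides
genuine sampling variability and is used where that variability is the
object of study (null calibration, CI coverage).

**Optical tier** (`simulate_recording`): the latent drives ΔHbO
(default 3 µM fluctuation scale); ΔHbR = −0.3·ΔHbO plus independent
band-limited noise (0.2 relative). Concentrations map to ΔOD through the
same forward Beer–Lambert model the pipeline inverts. Added in OD units:
cardiac pulsation (0.008, shared phase, first harmonic, smoothly drifting
rate inside 70–200 bpm, absent on "dead" channels), respiration
(5e-4, 0.6–1.2 Hz), a Mayer wave (3e-4 at 0.1 Hz), slow drift synthesized
below 0.005 Hz (0.005 RMS), and white noise (0.002). Motion epochs
(≥ 2 s, Poisson ½/min) multiply the noise 30× and suppress cardiac to 5%;
spikes (< 2 s, 1/min) add decaying transients. Intensity = exp(−ΔOD)
around a unit baseline (absolute intensity scale is irrelevant to the
change-based analysis). The nuisance amplitudes are plausible optical
scales for neonatal recordings chosen once; they put the in-band
signal-to-nuisance ratio high enough that the clean-condition oracle is
meaningful, while motion epochs remain catastrophic for windowed SCI as
they should be.

**Cohort structure.** Demographics are truncated normals matching the
reference cohort (GA 39.08 ± 1.31 wk in [36, 42.2]; PNA 22.93 ± 11.20 h,
≥ 4 — note the truncation raises the realized mean to ≈ 24 h; head
circumference 347 ± 17 mm in [310, 380]; sex Bernoulli(½)). The true
correlation matrix is block-structured — left-intra 0.5, right-intra 0.4,
inter tanh(atanh(0.25) + β_PNA·(PNA − mean)) with β_PNA = 0.004 z/h by
default (the left > right > inter ordering mirrors the structure the
analysis is meant to detect; effect magnitudes are free parameters used
for recovery testing, as no empirical magnitudes are available to match).
Cohort-level heterogeneity is added in Fisher-z space: a per-subject
offset (SD 0.05), a per-sex offset (SD 0.02) and symmetric per-pair
jitter (SD 0.05), then projection to the nearest positive semi-definite
correlation matrix. Without this heterogeneity the recovery experiment
would be degenerate (zero residual variance). All randomness flows from
one root seed through per-subject substreams; identical seeds give
bit-identical cohorts.

**What passing synthetic tests does not show.** The generator's
hemodynamics are Gaussian and stationary with block-constant
connectivity; real neonatal data have sleep-state dynamics,
non-stationary vascular physiology, optode-coupling drift, and spatially
structured artifacts none of which are modeled. Recovery of the injected
age slope demonstrates that the estimator chain is consistent and
calibrated under the assumed model, not that the model is right for any
particular cohort.

## Validation experiments and problem sizes

Statistical validation runs on the connectivity tier so realistic sample
sizes fit in minutes: the null-calibration experiment uses 200 replicate
cohorts of 41 subjects at 120 s each (global null, identity correlation)
and checks that the pooled FDR rejection proportion stays within twice
its Monte-Carlo error of the nominal 0.05; the recovery experiment uses
20 replicate cohorts of 200 subjects at 300 s and checks that the
hemispheric model's 95% CI covers the injected interhemispheric PNA
slope in ≥ 90% of replicates. The end-to-end oracle runs the full optical
tier: a noiseless, motion-free 600-s recording must come through the
entire pipeline with every pairwise correlation within 0.05 of the
generator's target, and under default (noisy) conditions every generated
motion epoch must be disjoint from every returned motion-free segment.
`scripts/acceptance.py` recomputes all of these from scratch.

## Known limitations

* The 0.01 Hz high-pass corner is nominal for segments shorter than
  100 s; the minimum-segment rule (50 s) admits segments where the corner
  is unresolvable (logged, as configured).
* The PSP normalization is package-defined; the 0.03 threshold is a
  default on this scale, not a universal constant.
* MixedLM p-values for the fixed effects are Wald/normal-based; no
  small-sample dof correction is applied, and the residual-based dof is
  reported alongside.
* With 2 sex levels the sex random intercept is weakly identified; a
  config switch (`sex_as_fixed`) refits sex as a fixed covariate for
  sensitivity analysis.
* SNIRF support covers the continuous-wave subset this pipeline needs
  (intensity time series, measurement list, probe wavelengths, metadata
  tags), not the full standard.
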