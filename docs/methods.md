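# Methods

`hrca` implements a complete, testable analogue of a barium-versus-water
comparison of high resolution cervical auscultation (HRCA) signals: a
synthetic cohort generator with known ground truth, a signal-conditioning
chain, a 36-feature representation, a per-feature linear mixed-model screen,
and a repeated-holdout classifier battery.  This note records the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic tiers can and cannot say about real recordings.

## The scientific setup

Swallowing vibrations and sounds are recorded from the anterior neck with a
tri-axial accelerometer (anterior–posterior AP, superior–inferior SI,
medial–lateral ML) and a contact microphone (MIC), hardware band-passed
0.1–3000 Hz and digitized at 20 kHz.  Thin-liquid barium swallows are
segmented frame-accurately against videofluoroscopy; water swallows — where no
imaging is available — are segmented by an operator push-button and are
therefore systematically *over-long*: they contain the true swallow plus
padding of non-swallow signal on both sides.  The analysis question is whether
any of 36 per-swallow signal features (9 features × 4 channels) differ
systematically between the two materials, and whether classifiers can predict
the material from the features at better than chance.

## Synthetic cohort generator

### Signal tier

Each swallow segment is built, per channel, as

    AR baseline noise  (+ low-frequency drift on AP/SI/ML)
      + band-limited vibration bursts inside the true swallow interval
      -> hardware band-pass 0.1–3000 Hz  -> x participant gain

* **Design.**  The default cohort replicates the analyzed design: 19
  participants, 90 barium and 95 water swallows (185 total).  Water swallows
  are 5 per participant; barium counts are spread as evenly as possible
  (fourteen 5s and five 4s).  The published source does not state the
  per-participant breakdown, so the even allocation is this package's choice.
* **Durations.**  True swallow duration ~ N(1.0 s, 0.25 s), truncated at
  0.3 s, for both materials; water segments add pre- and post-padding
  ~ N(0.75 s, 0.25 s) per end, so water *segments* average ≈ 2.5 s while
  barium segments equal the true swallow.  These calibrations are stand-ins
  chosen to be clinically plausible (single 3 mL thin-liquid swallows take on
  the order of a second; push-button segments a few seconds); the source's
  duration table was not machine-readable.
* **Sensor noise.**  AR(2) with coefficients (0.5, −0.25) and innovation
  variance 0.01 per channel — a mildly colored, stationary baseline.
  Stability (roots inside the unit circle) is enforced at construction.
* **Drift.**  Gaussian noise low-passed below 2 Hz, scaled to RMS 0.5, added
  to the accelerometer channels only: head motion does not register on the
  contact microphone.
* **Bursts.**  2–3 band-limited noise bursts with Gaussian envelopes inside
  the true swallow interval; microphone band 100–1500 Hz, accelerometer bands
  50–500 Hz.  Bursts are statistical stand-ins for swallow vibrations, not
  biomechanics.
* **Participant structure.**  A per-participant log-normal gain
  (`participant_gain_sd = 0.1`) multiplies all of a participant's channels —
  the simplest mechanism that clusters scale-sensitive features within
  participants.
* **Material effects.**  Configured effects are realized through burst-model
  knobs on water swallows only: amplitude scaling (moves `std_dev`), band
  widening (raises wavelet entropy), band narrowing (lowers Lempel-Ziv
  complexity / raises entropy-rate regularity).  The padding regime itself
  also moves the information-theoretic features — that is the real
  segmentation mechanism and is deliberately present whenever padding is
  nonzero.  `null_signal_config()` zeroes *both* the effect knobs and the
  padding, giving a cohort where water and barium are statistically
  identical; that is the configuration under which the downstream screen
  should reject at its nominal rate.

### Feature tier

For testing the statistical stages with *exactly* known effects, feature
tables are drawn directly from the screen's own generating model

    y_ijf = beta0_f + beta1_f * I(water) + u_if + e_ijf

with the participant effect and residual induced by a shared 8-factor latent
structure: row-normalized loadings carry 98% of each feature's
within-participant variance and idiosyncratic noise the remaining 2%
(`feature_idio_var = 0.02`).  Loadings are scaled so the within-participant SD
is exactly 1 — hence planted standardized shifts equal `beta1` — and the
per-feature random-intercept SD is `feature_random_sd = 0.5` (intra-class
correlation 0.2).  The factor structure is what makes the first 8 principal
components of the standardized table explain > 97% of variance, matching the
dimensionality-reduction behavior the analysis relies on.

The default planted-effect set is 8 feature×channel combinations consistent
with the reported rejection pattern — four on MIC (`std_dev`,
`wavelet_entropy` (+), `entropy_rate` (+), `lz_complexity` (−)),
`wavelet_entropy` (+) on AP/SI/ML, and `entropy_rate` (+) on SI — with a
default magnitude of 0.5 within-participant SDs.  The exact published set and
p-values were not machine-readable; this designation is a documented stand-in.

## Preprocessing chain

Per channel, in the narrative order of the original acquisition description:

1. **Downsampling** to 4 kHz by polyphase anti-aliased resampling
   (`scipy.signal.resample_poly`); output length is `ceil(n·fs_out/fs_in)`.
2. **Whitening.**  An AR model of each sensor's zero-input baseline is fit by
   Yule-Walker (MLE autocovariance, guaranteeing stability), with order
   selected by BIC over 0..10; the whitening filter is the prediction-error
   FIR `[1, −a_1, …, −a_p]`.  AR models are fit on the *downsampled* baseline
   so the filter matches the rate at which it is applied.  In synthetic runs
   the baseline comes from `generate_baseline`; for real data a baseline
   recording must be supplied explicitly (no silent auto-detection).
3. **Spline detrending** (accelerometer channels only): a least-squares
   B-spline of order 4 (cubic) with uniform interior knots every 0.5 s is
   subtracted.  0.5 s knots track head movement (< 2 Hz) while leaving
   swallow transients; cubic order means polynomials up to degree 3 are
   removed exactly.  Segments shorter than two knot intervals get
   proportionally tighter knots (duration/3) rather than an error.
4. **Wavelet denoising** (all channels): multilevel discrete Meyer (`dmey`)
   decomposition, up to 10 levels but capped at the signal's maximum depth
   (a 1 s segment at 4 kHz supports 6 levels of the 62-tap `dmey` filter);
   soft thresholding of detail coefficients at the universal threshold
   σ̂·sqrt(2 ln N), σ̂ estimated from the median absolute deviation of the
   finest detail level.  "10 levels" is an interpretation of the original
   "10th-order Meyer wavelet", which could also mean a filter order; the
   decomposition-depth reading is the conventional one for discrete wavelet
   denoising.

**Numerical conventions for `dmey`.**  PyWavelets' `dmey` filter bank is a
62-tap truncation of the Meyer wavelet whose filters have squared norm
≈ 1.0022 and whose reconstruction error is ≈ 0.3% relative — inherent to the
truncation.  The package renormalizes the filters to unit norm (making the
periodized transform energy-preserving to ≈ 4·10⁻⁴) and caps the
reconstruction's energy at the input's, so denoising is a strict contraction
as soft thresholding implies.  Signals are zero-padded to a multiple of
2^levels before the periodized transform and trimmed afterwards.

## Features

Nine features per channel, 36 per swallow, named `<feature>_<channel>`:

| domain | features | conventions |
|---|---|---|
| time | `std_dev`, `skewness`, `kurtosis` | sample SD (ddof 1); kurtosis non-excess (Gaussian → 3); constant signal → SD 0, skew/kurt NaN |
| frequency | `peak_frequency`, `spectral_centroid`, `bandwidth` | Welch PSD, Hann, 256-sample segments, 50% overlap (≥ 15 Hz resolution at 4 kHz); centroid Σf·P/ΣP; bandwidth RMS deviation about the centroid |
| time-frequency | `wavelet_entropy` | Shannon entropy (nats) of relative subband energies (final approximation + all details) of the `dmey` decomposition; scale-invariant |
| information-theoretic | `lz_complexity`, `entropy_rate` | see below |

**Lempel-Ziv complexity.**  The signal is binarized at its median (ties → 1,
so constant stretches don't flip class), parsed by the LZ76
exhaustive-history rule, and normalized as C = c(n)·log₂(n)/n, which → 1 for
i.i.d. random sequences.  Note the exhaustive history of a constant sequence
is {0, 00…0}: c = 2, the minimal value for n ≥ 2.

**Entropy rate (regularity index).**  The de-meaned signal is quantized into
10 uniform amplitude bins; for word lengths L = 1..10 the corrected
conditional entropy CCE(L) = E(L) − E(L−1) + perc(L)·E(1) is computed, where
perc(L) is the fraction of L-words seen exactly once — the correction that
prevents conditional entropy from artifactually vanishing as L grows on short
records.  The index is ρ = 1 − min_L CCE(L)/E(1) ∈ [0, 1]; higher = more
regular.  A constant signal is maximally regular (ρ = 1) by convention.  The
documented minimum input length is 1000 samples.

**Missing-value policy.**  Degenerate channels yield NaN for the affected
features; the screen drops missing rows per feature (not listwise) and the
classifier battery drops incomplete rows, both with logged counts.

## Statistical screen

One linear mixed model per feature: material fixed effect (water − barium),
participant random intercept, REML estimation (statsmodels `MixedLM`),
two-sided Wald test with a normal reference at α = 0.05, and *no*
multiple-testing correction — the screen intentionally reports raw
per-feature rejections.  The original analysis (SAS) likely used a
small-sample denominator-df correction; with 185 observations and 19 groups
the difference is immaterial, and the normal reference keeps the contract
implementation-neutral.  If the REML optimizer fails, a profile-likelihood
grid over the variance ratio σ_u²/σ² (closed-form GLS per grid point via the
Woodbury identity) is used before a feature is declared unscreened.

## Classifier battery

Linear SVM (C = 1, no tuning), Gaussian Naive Bayes, and 2-cluster K-means
used as a classifier (clusters labeled by training majority, ties to the
lexicographically smallest label; test points to the nearest centroid).
Evaluation: 2000 iterations of uniform random swallow-level 70/30 splits —
without stratification and *without participant grouping*, deliberately
replicating the original protocol's participant leakage.  Standardization and
PCA (8 components) are fit on the training split only; the original may have
fit PCA before splitting, and the leak-free protocol is this package's
documented divergence.  Five measures per split — overall accuracy,
sensitivity to each material, predictive value of each material's
predictions — are averaged over iterations; splits missing a class in
training are redrawn and undefined ratios (empty predicted class) are
excluded from their average, both logged.

Two properties of this protocol are worth knowing when reading null results.
First, repeated holdout on a single finite sample estimates that sample's
separability, not the population's: a given null draw carries chance
material separation that every split shares, so iteration-averaged metrics
scatter around chance by a few percentage points from draw to draw.  Second,
the estimates are slightly pessimistic under the null — a noise pattern
over-represented in the training split is necessarily under-represented in
its complementary test split, which biases holdout accuracy a little below
50%.  Both effects are inherent to the published protocol, which the package
reproduces as specified.

## What the synthetic tiers do and do not show

The feature-tier generator draws from exactly the model the screen fits, so
screen calibration (type-I ≈ 0.05) and recovery results there validate the
*estimator and protocol*, not the realism of HRCA data.  The signal tier adds
the acquisition chain's structure (coloring, drift, bursts, gain clustering,
segmentation padding) but its bursts are statistical stand-ins: no
biomechanics, no bolus flow, no aspiration events, no VFSS imagery.  Passing
tests therefore demonstrate that the pipeline measures what it claims on data
with known truth — they do not certify performance on clinical recordings.

## Problem sizes used in the shipped checks

Study-replica size (185 swallows, 19 participants) everywhere it matters:
PCA calibration over 20 seeds, screen recovery over 50 replicates, null
classification over the full 2000-iteration protocol, and screen type-I
calibration over 1000 single-feature null replicates at study scale (a
single-feature replicate estimates the same per-feature rejection rate as a
36-column table at 1/36 the cost).  Unit tests use smaller cohorts where the
property under test does not depend on scale.

## Known limitations

* The duration calibrations, effect-set designation, and effect magnitudes
  are documented stand-ins, not published values.
* "10th-order Meyer" is interpreted as decomposition depth; a filter-order
  reading would change subband boundaries slightly.
* Whether whitening preceded downsampling in the original system is
  unstated; this chain downsamples first.
* The signal-tier effect knobs move features only approximately (burst
  amplitude/bandwidth are coarse actuators); exact effect sizes are only
  available on the feature tier, by design.
* The classifier protocol replicates participant leakage across splits on
  purpose; grouped splitting would give more conservative estimates on real
  cohorts.
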