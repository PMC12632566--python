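# Methods

This note documents the generative model behind the synthetic sessions,
the estimators implemented on top of them, the numerical choices that
matter, and what passing the test suite does and does not establish about
real data.

## The synthetic session model

A session is a triplet (multichannel LFP, tract-variable kinematics,
annotations) built from one latent object: a complex analytic theta
carrier z(t).

**Theta carrier.** Gaussian white noise shaped in the frequency domain by
a Gaussian envelope centered on `theta_f0` (default 8.2 Hz) with FWHM
`theta_bandwidth` (default 1.5 Hz), positive frequencies only, normalized
to unit variance of its real part. `bandwidth -> 0` degenerates to a pure
sinusoid with a seeded random phase. The bandwidth is the single knob for
rhythm *periodicity*: the autocorrelation envelope of a Gaussian-spectrum
process decays like exp(-(2π σ_f τ)²/2), so the secondary ACF peak at one
period falls monotonically with bandwidth — the property the periodicity
statistics measure.

**Channels.** Channel c is
`theta_amplitude * Re(z e^{-i δ_c}) + background + hg`, where δ_c is the
channel's phase offset: channel 0 (the most ventral site, the reference)
is fixed at 0; an `antiphase_fraction` subset sits at π; the rest scatter
around 0 (SD 0.15 rad); an optional linear dorsoventral gradient
(`phase_gradient_rad_per_mm`) can be added for sequence analyses. The
background is 1/f^χ noise (χ = 1.5 by default; the exponent the spectral
parameterization must recover). During silence each non-reference channel
runs its own independent theta oscillator; a smooth weight blends it into
the shared carrier starting 200 ms before every utterance onset
(`coherence_lead_s`), so inter-site coherence rises only around speech,
with a preparatory lead. The blend transition briefly *lowers* the
within-window phase-locking value around −0.3 s; this is an artifact of
linear mixing of two independent narrowband processes and is visible in
coherograms as a shallow dip just before onset.

**High-gamma.** Band-limited (70–150 Hz) noise whose envelope is
multiplied by `1 + pac_depth cos(φ_c − pac_phase)`, with φ_c the channel's
local theta phase. Default `pac_depth` 0.4 and `pac_phase` 208°: the
articulatory preferred phase is 301° and the articulatory-vs-neural offset
is 93°, which places the HG maximum 28° after the trough — "near the
trough" on the phase convention 0 = peak, 180° = trough. A per-syllable,
per-channel multiplicative gain (`syllable_code_strength`) applied in a
240 ms window around each nucleus gives the HG patterns decodable syllable
content.

**Gestures and annotations.** Utterances of varying length (±25% around a
2 s mean) alternate with silent gaps; syllables tile each utterance at
`syllable_rate` (default 4/s). Every theta cycle inside an utterance
carries a gesture scheduled at the phase `ac_preferred_phase` (301°) of
that cycle; amplitude is graded 1.0 at the cycle nearest the syllable
nucleus, 0.8 at the cycles nearest nucleus ± `triplet_spacing_s` (0.125 s,
the onset/coda flanks), `background_gesture_amplitude` (0.7) elsewhere.
Each scheduled cycle is skipped with probability `cycle_skip_prob`
(default 0.11), so the realized pulse rate is `theta_f0 (1 − skip)` ≈
7.3/s; the fast-speech condition is emulated by a denser scheduler
(`theta_f0` = 8.66, skip = 0, syllable rate 5.8/s). Gestures are Gaussian
velocity bumps (σ = 16 ms) in 2–4 randomly chosen tract variables, scaled
by √(2/k) so the summed squared-velocity pulse height does not depend on
how many articulators k share the gesture. Positions integrate the
velocities with a leaky trapezoidal rule — trapezoidal specifically, so
that central-difference differentiation recovers a time-centered velocity
(a one-sided accumulator shifts the recovered pulses half a kinematic
sample, −5 ms ≈ −15° of theta phase). Annotations record the *realized*
(cycle-snapped) onset/nucleus/coda times, which is what forced alignment
of produced speech would report.

**Error trials.** A fraction of utterances (default 0.15) is flagged
non-fluent. Within them, every channel's local theta (and therefore its
HG coupling) rotates by an independent random angle (SD
`error_phase_jitter_sd`, default 60°), and kinematic pulses are jittered
in time by the equivalent phase amount. This degrades the theta–movement
modulation index and makes the preferred phase inconsistent across sites —
the two signatures the fluency contrast measures — without changing theta
power.

## Estimators and numerical choices

- **Welch PSD**: 1 s Hann segments, 50% overlap, ×2 zero-padding
  (0.5 Hz grid below 30 Hz), averaged over event-locked epochs.
- **Spectral parameterization**: log10-power = (offset + slope·log10 f) +
  Σ Gaussians, knee-free. The aperiodic line is fit robustly (refit on the
  below-median residuals so peaks cannot bias the slope), peaks extracted
  iteratively (largest residual first) until 4 peaks, or the residual
  maximum falls below max(2 residual SDs, 0.1 log10 units); then a joint
  bounded least-squares refit. A broad oscillatory bump occasionally
  splits into two narrow Gaussians; `band_peak_center` therefore reports
  the (height × width)-weighted centroid of in-band peaks, which recovers
  the generator's 8.2 Hz to ±0.2 Hz on 60 s data across seeds.
- **Band-limited analytic signals**: Hamming-window FIR (transition 1 Hz,
  ~3.3 fs taps), `filtfilt`, Hilbert transform. This fixes the phase
  convention (0 = peak, π = trough) used everywhere downstream.
- **Coherograms**: per-frequency Morlet phases (5 cycles); coherence is
  the within-window (0.5 s, 0.05 s step) mean resultant length of the
  phase differences, averaged over events. The window must cover ≥ 2
  cycles of the lowest frequency, so the default grid starts at 4 Hz; a
  3 Hz floor requires a longer window. Narrowband signals drift slowly, so
  the within-window null floor is high; the *change vs pre-event baseline*
  is the meaningful statistic. Group statistics aggregate pairs within
  subject, then t-test across subjects per (time, frequency), BH-FDR.
- **Modulation index**: 24 bins of 15° for both HG and AC coupling;
  MI = KL(profile‖uniform)/log 24 ∈ [0, 1]. Surrogates circularly shift
  the phase series by ≥ 1 s; with a speech mask, shifts are applied before
  masking. p = (1 + #{MI_surr ≥ MI_obs})/(1 + n_surr). Note that a
  *perfectly periodic* phase series is rotation-invariant, so surrogate
  tests are only meaningful on stochastic rhythms — which is also why the
  generator's carrier is stochastic.
- **AC**: 20 Hz Butterworth low-pass of trajectories, central-difference
  velocity, squared sum, 15 ms Gaussian smoothing. Pulse threshold:
  within-utterance median + 0.5 MAD, minimum separation 60 ms. The
  low-pass/smoothing/threshold triple was chosen so that gesture pulses at
  7–9/s remain individually resolvable; heavier smoothing or a
  median + 1 MAD threshold clips the smaller onset/coda gestures and
  biases the estimated pulse rate down by ~2 pulses/s.
- **mTRF**: lag-expanded ridge regression (lags −0.6…0.6 s by default),
  solved per training fold by one SVD (all penalties from the same
  decomposition), λ grid 10⁻²…10⁶ chosen by blocked (contiguous-fold)
  cross-validated R². Unique variance: ΔR² between full and
  reduced models under the same folds and λ protocol.
- **Phase warping**: unwrapped phase per epoch, anchor trough mapped to
  axis 0, linear interpolation onto [−9π, 7π] (default 10 points per π,
  finer for decoding); brief non-monotonic phase slips are repaired by a
  running maximum, slips longer than 50 ms drop the trial (logged). Trials
  not covering the full axis are edge-flagged, never extrapolated.
  Surrogate bands for phase-locked averages come from per-trial circular
  shifts of the warped trace by ≥ 1 cycle (50 surrogates, 2.5/97.5
  percentiles).
- **Decoding**: per phase bin (0.3 rad window), mean warped HG per
  electrode, z-scored within training folds, linear SVC (one-vs-rest),
  stratified 5-fold CV; classes need ≥ 10 repetitions; the shuffle null
  reuses the same folds; BH-FDR across bins. Significant-bin combination
  sums per-trial decision scores weighted by bin accuracy.
- **Sequences**: latency = peak of the normalized cross-correlogram vs
  the grand-average peri-AC profile (ties → smallest |lag|); phases for
  the latency–phase analyses are each site's HG preferred phase on the
  *reference site's* theta clock (a site activating later in the cycle has
  a larger phase — the orientation in which the latency–phase correlation
  is positive). The pairwise lag–phase correlation is computed through the
  origin because pair differences are antisymmetric, making it invariant
  to each pair's arbitrary orientation; significance by electrode-label
  permutation.
- **Circular statistics**: Rayleigh test with the standard finite-n
  p-value approximation; two-sample Watson U² and the two-sample
  concentration (dispersion) test use permutation p-values, which remain
  valid at any concentration; circular–linear correlation is the multiple
  correlation of the linear variable on (cos φ, sin φ) with both a
  permutation and the asymptotic χ²(2) p-value.
- **Matched resampling**: greedy nearest-neighbor draws without
  replacement in standardized (syllable rate, duration) space, 200
  resamples; subjects with < 10 error trials are flagged excluded.

## Problem sizes

Tests and the acceptance script run on scaled-down study conditions chosen
to keep every Monte-Carlo check well-powered on a single CPU: sessions of
60–150 s with 2–16 channels, 200-run calibrations with 199 surrogates
each, 20-seed spectral recovery, decoders on ~100–300 trials with 8–16
electrodes. These sizes are the package's declared defaults for its
synthetic studies; all estimators accept full-size inputs unchanged.

## What passing the tests shows — and what it does not

The synthetic generator reproduces the *statistical couplings* the
analyses assume: a narrowband stochastic rhythm over 1/f background,
envelope and movement phase-locking, syllable-structured gesture triplets,
skipped cycles, phase-disorganized error trials. Passing the suite shows
the estimators recover injected parameters under those conditions and that
the surrogate tests are calibrated. It does not validate the analyses
against non-stationary rhythm frequency, volume conduction between
neighboring channels (the < 15 mm exclusion exists for real data but the
generator does not model conduction), movement or epileptiform artifacts,
imperfect forced alignment, or acoustic contamination of field potentials.
Real-data effect sizes (modulation indices, decoding accuracies,
consistency values) will differ from the synthetic ones, which are set for
test power rather than biological realism.

## Known limitations

- The coherence estimator's within-window variant has a high bias floor on
  narrowband signals; the cross-trial variant (available by option) has a
  cleaner null but needs many events.
- The generator's fast-speech condition raises the cycle rate rather than
  truly decoupling pulse rate from the rhythm; real articulation can
  exceed the instantaneous oscillation rate.
- Phase-offset classes (near-zero / antiphase) use fixed ±45° windows;
  sites near the class boundaries are assigned, not flagged ambiguous.
- The error-trial model disorganizes phase only; it does not model the
  behavioral structure of repairs (restarts, prolongations).
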