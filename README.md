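# thetaspeech

Analysis of the sensorimotor **theta rhythm (6–10 Hz)** that times speech
movements, as measured with intracranial field potentials (ECoG) and
vocal-tract kinematics. The package is aimed at researchers in speech motor
control and electrophysiology who want a tested, end-to-end implementation
of this analysis family — and a synthetic-data generator that makes every
stage verifiable without access to patient recordings.

## What it computes

During fluent speech, a stable ~8.2 Hz oscillation in ventral sensorimotor
cortex appears to act as a timing scaffold: sites oscillate coherently
(mostly in phase, a subset in antiphase), population activity (high-gamma
amplitude, HG) is maximal near the theta trough, and articulatory gestures
— pulses of the **Articulatory Change** statistic,
AC(t) = Σ_v (dx_v/dt)², summed over tract variables v — lock to a late
theta phase (~301°), about a quarter cycle (~93°) after the HG burst.
The package implements each link in that chain:

| module | contents |
| --- | --- |
| `synthgen` | synthetic sessions: stochastic theta carrier over 1/f background, per-channel phase offsets (antiphase subset, optional dorsoventral gradient), theta-modulated HG, cycle-locked gesture pulses with skipped cycles and error trials |
| `spectral` | event-locked Welch PSD, 1/f-corrected peak detection (>3σ prominence), aperiodic+Gaussian-peaks decomposition, Morlet peri-event spectrograms (relative / baseline-dB) |
| `phasecoh` | zero-phase band-limited analytic signals, sliding-window phase-locking coherograms, hierarchical coherence-change statistics with BH-FDR, inter-site phase-offset maps (near-zero / antiphase classes, <15 mm exclusion) |
| `coupling` | Tort modulation index over 24 × 15° phase bins, circular-shift surrogate inference, preferred phase, BH-FDR |
| `kinematics` | AC, pulse/inter-peak-interval statistics, ridge mTRF encoding models (phonemes→AC, kinematics→HG) with cross-validated unique variance |
| `phasewarp` | trough anchoring, warping of epochs onto the uniform phase axis [−9π, 7π], phase-locked averages with surrogate bands, sliding-window (0.3 rad) linear-SVM syllable decoding with weighted bin combination |
| `sequences` | cross-correlogram latencies, circular–linear correlation, pairwise lag–phase correlation, PCA state-space trajectories |
| `rhythmstats` | ACF periodicity (secondary-peak magnitude), rate/periodicity relations, matched-trial resampling, fluent-vs-error coupling contrasts, circular tests (Rayleigh, Watson U², Fisher dispersion) |

Phase convention throughout: 0 = waveform positive peak, π = trough.

## Worked example

`examples/coupling_analysis.py` generates a 60 s synthetic session and
measures the coupling of one sensorimotor site:

```
HG-PAC:      MI = 0.0088, p = 0.0020, preferred phase = 205 deg (injected 208)
Theta-AC:    MI = 0.1119, p = 0.0020, preferred phase = 301 deg (injected 301)
AC - HG offset: 96 deg (movement follows the population-activity burst by ~a quarter cycle)
```

The modulation index (MI) is the normalized KL divergence of the
phase-binned amplitude profile from uniform; p-values come from circular
shifts of the phase series, which preserve its autocorrelation while
destroying the alignment. The recovered preferred phases match the
injected generator parameters: HG peaks just after the trough, AC a
quarter cycle later.

`examples/phase_warped_decoding.py` shows the phase-warped view:

```
230 syllable epochs on the phase axis [-9pi, 7pi]
AC exceeds the null band at 40% of phase points; peak at 302 deg of the anchor cycle (injected 301)
12-class decoding (chance 8.33%): peak bin accuracy 57.8%, combined over 8 significant bins: 90.0%
```

The other examples cover session simulation and persistence
(`simulate_session.py`), spectral parameterization
(`spectral_analysis.py`), and fluency/periodicity statistics
(`fluency_and_periodicity.py`).

## Scope notes

The generator emulates the *statistical structure* of speech ECoG +
kinematics sessions, not speech itself: no acoustics, no phonetic detail
beyond consonant–vowel timing, no volume conduction. Acoustic-to-
articulatory inversion and electrode localization from imaging are out of
scope. See `docs/methods.md` for the model, parameter choices, and
limitations.
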