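"""Band-limited analytic signals, sliding-window phase-locking coherograms,
coherence-change statistics, and inter-site phase-offset mapping.

Phase convention (fixed here for the whole package): the analytic phase of
the zero-phase band-passed signal, 0 at the waveform positive peak and
+/-pi at the trough.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .circstats import circ_mean, wrap
from .containers import BandSignal, Coherogram, EventTable
from .coupling import bh_fdr

__all__ = [
    "band_analytic",
    "sliding_plv_coherogram",
    "coherence_change_stats",
    "phase_offset_map",
]

THETA_BAND = (6.0, 10.0)


def band_analytic(sig, fs, band=THETA_BAND, transition_hz: float = 1.0) -> BandSignal:
    """Zero-phase FIR band-pass + Hilbert analytic amplitude and phase.

    Hamming-windowed FIR, filtered forward and backward (zero group delay
    by construction).
    """
    sig = np.asarray(sig, dtype=float)
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    numtaps = int(3.3 * fs / transition_hz)
    numtaps += 1 - numtaps % 2  # odd
    if sig.size < 3 * numtaps:
        raise ValueError("signal must be at least 3 filter lengths long")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    filt = sps.filtfilt(taps, [1.0], sig)
    analytic = sps.hilbert(filt)
    return BandSignal(band=(lo, hi), amplitude=np.abs(analytic),
                      phase=np.angle(analytic), fs=fs)


def _morlet_phases(sig, fs, freqs, n_cycles):
    from mne.time_frequency import tfr_array_morlet

    arr = np.asarray(sig, dtype=float)[None, None, :]
    cplx = tfr_array_morlet(arr, sfreq=fs, freqs=np.asarray(freqs, float),
                            n_cycles=n_cycles, output="complex")
    return np.angle(cplx[0, 0])  # (n_freqs, n_samples)


def sliding_plv_coherogram(sig_ref, sig_other, fs, events: EventTable,
                           freqs=None, window_s: float = 0.5,
                           step_s: float = 0.05, epoch_window=(-1.5, 3.0),
                           n_cycles: float = 5.0,
                           baseline_window=(-1.0, 0.0)) -> Coherogram:
    """Sliding-window phase-locking coherogram between two sites.

    Per frequency, instantaneous phases come from Morlet convolution; per
    sliding window the coherence is the mean resultant length of the
    within-window phase differences, averaged across events.  The window
    must span at least two cycles of the lowest frequency.
    """
    if freqs is None:
        freqs = np.geomspace(4.0, 50.0, 24)
    freqs = np.asarray(freqs, dtype=float)
    if window_s * freqs.min() < 2.0:
        raise ValueError("window must span >= 2 cycles of the lowest frequency")
    ph_a = _morlet_phases(sig_ref, fs, freqs, n_cycles)
    ph_b = _morlet_phases(sig_other, fs, freqs, n_cycles)
    dphi = np.exp(1j * (ph_a - ph_b))  # unit phasors of the phase difference

    w0, w1 = epoch_window
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    starts_rel = np.arange(int(round(w0 * fs)), int(round(w1 * fs)) - nwin + 1, nstep)
    times = (starts_rel + nwin / 2) / fs

    onsets = events.utterances["onset_s"].to_numpy()
    acc = np.zeros((freqs.size, starts_rel.size))
    n_ev = 0
    for t in onsets:
        i = int(round(t * fs))
        if i + starts_rel[0] < 0 or i + starts_rel[-1] + nwin > dphi.shape[1]:
            continue
        for k, s in enumerate(starts_rel):
            seg = dphi[:, i + s: i + s + nwin]
            acc[:, k] += np.abs(seg.mean(axis=1))
        n_ev += 1
    if n_ev == 0:
        raise ValueError("no events fit inside the recording")
    return Coherogram(times=times, freqs=freqs, coherence=acc / n_ev,
                      n_pairs=1, baseline_window=tuple(baseline_window))


def coherence_change_stats(coherograms, subjects, baseline_window=(-1.0, 0.0),
                           q: float = 0.05):
    """Group-level coherence change versus the pre-event baseline.

    Per pair: coherence minus its baseline-window mean (per frequency).
    Hierarchical aggregation: pairs are averaged within subject, then a
    one-sample t-test across subjects is run per (frequency, time) point
    and Benjamini-Hochberg corrected at level ``q``.

    Returns ``(effect, p_values, mask)`` each of shape (n_freqs, n_times).
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need pairs from at least 2 subjects")
    t0, t1 = baseline_window
    changes = []
    for coh in coherograms:
        bsel = (coh.times >= t0) & (coh.times <= t1)
        if not bsel.any():
            raise ValueError("no baseline samples in coherogram")
        changes.append(coh.coherence - coh.coherence[:, bsel].mean(axis=1, keepdims=True))
    changes = np.asarray(changes)
    per_subject = np.stack([changes[subjects == s].mean(axis=0) for s in uniq])
    effect = per_subject.mean(axis=0)
    tstat, p = stats.ttest_1samp(per_subject, 0.0, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    mask, _ = bh_fdr(p.ravel(), q=q)
    return effect, p, mask.reshape(p.shape)


def phase_offset_map(phases, reference_channel: int, coords_mm,
                     speech_mask=None, min_dist_mm: float = 15.0,
                     ch_names=None) -> pd.DataFrame:
    """Mean theta-phase offset of each channel relative to a reference site.

    ``phases`` is (n_channels, n_samples) instantaneous phase (radians).
    The offset is the circular mean of the per-sample phase difference over
    ``speech_mask`` samples.  Channels are classified ``near-zero``
    (0 +/- 45 deg), ``antiphase`` (180 +/- 45 deg) or ``other``; channels
    closer than ``min_dist_mm`` to the reference are flagged excluded
    (volume-conduction guard) but still classified.
    """
    phases = np.asarray(phases, dtype=float)
    n_ch, n_samp = phases.shape
    if not 0 <= reference_channel < n_ch:
        raise ValueError("reference channel missing")
    coords = np.asarray(coords_mm, dtype=float).reshape(n_ch, 3)
    mask = np.ones(n_samp, bool) if speech_mask is None else np.asarray(speech_mask, bool)
    ref = phases[reference_channel][mask]
    rows = []
    for c in range(n_ch):
        d = phases[c][mask] - ref
        off = float(circ_mean(d))
        mrl = float(np.abs(np.exp(1j * d).mean()))
        a = abs(wrap(off))
        if a <= np.pi / 4:
            cls = "near-zero"
        elif a >= 3 * np.pi / 4:
            cls = "antiphase"
        else:
            cls = "other"
        dist = float(np.linalg.norm(coords[c] - coords[reference_channel]))
        rows.append(dict(
            channel=(ch_names[c] if ch_names is not None else c),
            offset_rad=off, mrl=mrl, offset_class=cls,
            dist_to_ref_mm=dist,
            excluded=(dist < min_dist_mm) and c != reference_channel,
        ))
    return pd.DataFrame(rows)
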