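"""Power spectra, 1/f-corrected peak detection, parametric decomposition,
and peri-event wavelet spectrograms.

The parametric decomposition models log10 power as an aperiodic component
``offset - exponent * log10(f)`` plus a sum of Gaussian peaks, extracted
iteratively (largest residual first) — the standard aperiodic/periodic
spectral parameterization.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, signal

from .containers import EventTable, Spectrum, SpectralFit

__all__ = [
    "welch_psd",
    "detect_spectral_peak",
    "parameterize_spectrum",
    "band_peak_center",
    "peri_event_spectrogram",
]


def welch_psd(sig, fs, window=(-1.0, 5.0), events: EventTable | None = None,
              segment_s: float = 1.0, overlap: float = 0.5) -> Spectrum:
    """Event-locked Welch power spectral density.

    Epochs ``[onset + window[0], onset + window[1]]`` are cut around each
    utterance onset (the whole signal if ``events`` is None) and the
    modified-periodogram average (1 s Hann segments, 50% overlap by
    default) is pooled over epochs.  Frequency resolution is
    ``1 / segment_s`` (0.5 Hz with 2 s segments; 1 Hz default, <= 0.5 Hz
    below 30 Hz when zero-padded — we pad x2 to hit 0.5 Hz).
    """
    sig = np.asarray(sig, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must be increasing")
    nper = int(round(segment_s * fs))
    nfft = 2 * nper  # 0.5 Hz resolution with 1 s segments
    if events is None:
        onsets = [max(0.0, -w0)]
    else:
        utt = events.utterances
        if len(utt) == 0:
            raise ValueError("no events")
        onsets = utt["onset_s"].to_numpy()
    psds, n_segments = [], 0
    for t in onsets:
        i0, i1 = int(round((t + w0) * fs)), int(round((t + w1) * fs))
        if i0 < 0 or i1 > sig.size:
            continue
        epoch = sig[i0:i1]
        if epoch.size < nper:
            raise ValueError("window longer than epoch")
        f, p = signal.welch(epoch, fs=fs, window="hann", nperseg=nper,
                            noverlap=int(nper * overlap), nfft=nfft,
                            detrend="constant")
        psds.append(p)
        n_segments += 1 + (epoch.size - nper) // (nper - int(nper * overlap))
    if not psds:
        raise ValueError("no epochs fit inside the recording")
    keep = f > 0
    return Spectrum(freqs=f[keep], power=np.mean(psds, axis=0)[keep],
                    n_segments=n_segments, window_s=segment_s)


def _aperiodic_fit(log_f, log_p, robust: bool = True):
    """Linear aperiodic fit in log-log space; optionally refit below-trend
    points only so narrowband peaks do not bias the slope."""
    A = np.column_stack([np.ones_like(log_f), log_f])
    coef, *_ = np.linalg.lstsq(A, log_p, rcond=None)
    if robust:
        resid = log_p - A @ coef
        keep = resid <= np.quantile(resid, 0.5)
        if keep.sum() >= 5:
            coef, *_ = np.linalg.lstsq(A[keep], log_p[keep], rcond=None)
    return coef  # (offset, slope); exponent = -slope


def detect_spectral_peak(spectrum: Spectrum, band, prominence_sd: float = 3.0):
    """Highest 1/f-corrected spectral peak in ``band``, or None.

    Fits and removes a log-log linear aperiodic trend, z-scores the
    residual over the whole spectrum, and returns ``(center_hz, z_height)``
    for the largest local maximum inside ``band`` whose z-scored prominence
    exceeds ``prominence_sd``; None otherwise.
    """
    lo, hi = band
    f, p = spectrum.freqs, spectrum.power
    sel = (f >= lo) & (f <= hi)
    if sel.sum() < 5:
        raise ValueError("band must contain at least 5 frequency bins")
    pos = p > 0
    if not pos.any():
        return None
    log_f, log_p = np.log10(f[pos]), np.log10(p[pos])
    off, slope = _aperiodic_fit(log_f, log_p)
    resid = log_p - (off + slope * log_f)
    sd = resid.std()
    if sd == 0:
        return None
    z = (resid - resid.mean()) / sd
    fb = f[pos]
    idx, props = signal.find_peaks(z, prominence=0.0)
    idx = idx[(fb[idx] >= lo) & (fb[idx] <= hi)]
    if idx.size == 0:
        return None
    best = idx[np.argmax(z[idx])]
    if z[best] <= prominence_sd:
        return None
    return float(fb[best]), float(z[best])


def _gaussian(f, center, height, width):
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


def parameterize_spectrum(spectrum: Spectrum, fit_range=(3.0, 30.0),
                          max_peaks: int = 4, peak_threshold_sd: float = 2.0,
                          min_peak_height: float = 0.1,
                          min_width_hz: float = 0.25) -> SpectralFit:
    """Aperiodic (1/f) + Gaussian-peaks decomposition of a power spectrum.

    Least-squares in log10-power space: first an aperiodic linear trend in
    log-log coordinates (fixed, knee-free mode), then Gaussian peaks
    extracted iteratively from the residual (largest first) until
    ``max_peaks`` are found or the residual maximum drops below
    ``peak_threshold_sd`` residual SDs or below the absolute floor
    ``min_peak_height`` (log10-power units), then a joint refit of all
    parameters.  Deterministic: identical input yields an identical fit.
    """
    lo, hi = fit_range
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    f = spectrum.freqs[sel]
    p = spectrum.power[sel]
    if f.size < 8:
        raise ValueError("fit_range must contain at least 8 bins")
    if np.any(p <= 0):
        raise ValueError("power must be > 0 over the fit range")
    log_f, log_p = np.log10(f), np.log10(p)
    off, slope = _aperiodic_fit(log_f, log_p)
    aper = off + slope * log_f
    resid = log_p - aper

    peaks = []
    work = resid.copy()
    for _ in range(max_peaks):
        sd = work.std()
        i = int(np.argmax(work))
        if sd == 0 or work[i] < max(peak_threshold_sd * sd, min_peak_height):
            break
        # half-height width guess
        half = work[i] / 2
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < len(work) - 1 and work[ri] > half:
            ri += 1
        guess_w = max((f[ri] - f[li]) / 2.355, min_width_hz)
        try:
            popt, _ = optimize.curve_fit(
                _gaussian, f, work, p0=[f[i], work[i], guess_w],
                bounds=([lo, 0, min_width_hz], [hi, 3 * work[i] + 1, (hi - lo)]),
                maxfev=5000)
        except RuntimeError as err:
            raise RuntimeError(f"peak fit failed to converge: {err}") from err
        peaks.append(tuple(popt))
        work = work - _gaussian(f, *popt)

    # joint refit of aperiodic + all peaks
    def model(f, *theta):
        out = theta[0] + theta[1] * np.log10(f)
        for k in range(len(peaks)):
            out = out + _gaussian(f, *theta[2 + 3 * k: 5 + 3 * k])
        return out

    p0 = [off, slope] + [v for pk in peaks for v in pk]
    if peaks:
        lb = [-np.inf, -np.inf] + [lo, 0, min_width_hz] * len(peaks)
        ub = [np.inf, 0.0] + [hi, np.inf, hi - lo] * len(peaks)
        try:
            theta, _ = optimize.curve_fit(model, f, log_p, p0=p0,
                                          bounds=(lb, ub), maxfev=10000)
        except RuntimeError as err:
            raise RuntimeError(f"joint spectral fit failed: {err}") from err
    else:
        theta = np.asarray(p0, dtype=float)
    fitted = model(f, *theta)
    ss_res = np.sum((log_p - fitted) ** 2)
    ss_tot = np.sum((log_p - log_p.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    out_peaks = [tuple(theta[2 + 3 * k: 5 + 3 * k]) for k in range(len(peaks))]
    out_peaks.sort(key=lambda pk: -pk[1])  # tallest first
    return SpectralFit(aperiodic_offset=float(theta[0]),
                       aperiodic_exponent=float(-theta[1]),
                       peaks=out_peaks, fit_range=(lo, hi),
                       goodness=float(max(min(r2, 1.0), 0.0)))


def band_peak_center(fit: SpectralFit, band=(5.0, 11.0)):
    """Center frequency of the oscillatory mass within a band.

    The (height x width)-weighted mean of the fitted Gaussian peak centers
    inside ``band`` — i.e. the centroid of the modeled oscillatory power.
    A broad oscillatory bump occasionally fits as two narrow Gaussians;
    the centroid summarizes it stably.  Returns None if no peak lies in
    the band.
    """
    sel = [(c, h, w) for c, h, w in fit.peaks if band[0] <= c <= band[1]]
    if not sel:
        return None
    weights = np.array([h * w for _, h, w in sel])
    centers = np.array([c for c, _, _ in sel])
    return float(np.sum(weights * centers) / np.sum(weights))


def peri_event_spectrogram(sig, fs, events: EventTable, freqs=None,
                           normalization: str = "relative",
                           window=(-1.5, 3.0), baseline=(-1.0, 0.0),
                           n_cycles: float = 6.0, decim: int = 10):
    """Morlet-wavelet power around utterance onsets, averaged over events.

    ``normalization='relative'``: power at each time point is divided by
    the summed power across frequencies (columns sum to 1).
    ``normalization='baseline'``: dB change relative to the mean power in
    the pre-event ``baseline`` window.

    Returns ``(times, freqs, matrix)`` with matrix shape (n_freqs, n_times).
    Events too close to the recording edge are dropped with a warning.
    """
    from mne.time_frequency import tfr_array_morlet

    sig = np.asarray(sig, dtype=float)
    if freqs is None:
        freqs = np.geomspace(3.0, 50.0, 30)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2:
        raise ValueError("freqs must lie below Nyquist")
    if normalization not in ("relative", "baseline"):
        raise ValueError("normalization must be 'relative' or 'baseline'")
    if normalization == "baseline" and baseline[0] < window[0]:
        raise ValueError("baseline must lie within the window")

    w0, w1 = window
    pad = n_cycles / freqs.min() / 2  # wavelet half-length at lowest freq
    epochs, dropped = [], 0
    n0 = int(round((w0 - pad) * fs))
    n1 = int(round((w1 + pad) * fs))
    for t in events.utterances["onset_s"].to_numpy():
        i = int(round(t * fs))
        if i + n0 < 0 or i + n1 > sig.size:
            dropped += 1
            continue
        epochs.append(sig[i + n0: i + n1])
    if dropped:
        warnings.warn(f"{dropped} events dropped near the recording edge")
    if not epochs:
        raise ValueError("no events fit inside the recording")
    arr = np.asarray(epochs)[:, None, :]  # (n_events, 1 channel, n_samples)
    power = tfr_array_morlet(arr, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
                             output="power", decim=decim)
    power = power.mean(axis=0)[0]  # (n_freqs, n_times)
    times = (np.arange(power.shape[1]) * decim + n0) / fs
    keep = (times >= w0) & (times <= w1)
    times, power = times[keep], power[:, keep]
    if normalization == "relative":
        out = power / power.sum(axis=0, keepdims=True)
    else:
        bsel = (times >= baseline[0]) & (times <= baseline[1])
        base = power[:, bsel].mean(axis=1, keepdims=True)
        out = 10.0 * np.log10(power / base)
    return times, freqs, out
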