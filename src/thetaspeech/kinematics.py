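"""Articulatory Change, pulse/interval analysis, and lagged linear (mTRF)
encoding models with unique-variance attribution.

Articulatory Change (AC) is the sum of squared velocities ("total speed")
across the measured tract variables; its local maxima ("pulses") index
constriction gestures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .containers import EventTable, TRFModel, TractKinematics

__all__ = [
    "articulatory_change",
    "ac_pulse_analysis",
    "impulse_train",
    "fit_mtrf",
    "unique_variance",
    "trf_response_profile",
]


def articulatory_change(kin: TractKinematics, smooth_ms: float = 15.0,
                        lowpass_hz: float | None = 20.0) -> np.ndarray:
    """Per-sample Articulatory Change: sum of squared velocities.

    Trajectories are optionally low-passed (4th-order Butterworth at
    ``lowpass_hz``), differentiated by central differences, squared and
    summed across tract variables, then smoothed with a Gaussian kernel of
    SD ``smooth_ms``.  Pass ``lowpass_hz=None`` and ``smooth_ms=0`` for the
    raw closed-form quantity.  The result is stored on ``kin.ac`` and
    returned.
    """
    x = kin.data
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if lowpass_hz is not None:
        if lowpass_hz >= kin.fs / 2:
            raise ValueError("lowpass_hz must be below Nyquist")
        b, a = sps.butter(4, lowpass_hz, fs=kin.fs)
        x = sps.filtfilt(b, a, x, axis=1)
    vel = np.gradient(x, axis=1) * kin.fs
    ac = np.sum(vel**2, axis=0)
    if smooth_ms and smooth_ms > 0:
        ac = ndimage.gaussian_filter1d(ac, sigma=smooth_ms / 1000.0 * kin.fs)
    ac = np.maximum(ac, 0.0)
    kin.ac = ac
    return ac


def ac_pulse_analysis(ac, fs, utterances, threshold: float | None = None,
                      min_separation_s: float = 0.06) -> dict:
    """AC pulse times, inter-peak intervals and per-utterance median rate.

    Pulses are local maxima above ``threshold`` (default: median + 0.5 MAD
    of the within-utterance AC — during continuous speech the AC is
    pulse-dense, so a stricter threshold clips the smaller onset/coda
    gestures) with minimum separation ``min_separation_s``, restricted to
    utterance spans.  The rate of an utterance is its pulse count divided
    by its duration; the summary rate is the median across utterances.
    """
    ac = np.asarray(ac, dtype=float)
    if (ac < 0).any():
        raise ValueError("ac must be nonnegative")
    utt = utterances.utterances if isinstance(utterances, EventTable) else pd.DataFrame(utterances)
    if len(utt) == 0:
        raise ValueError("utterances must be nonempty")
    spans = [(float(r.onset_s), float(r.offset_s)) for r in utt.itertuples()]
    if threshold is None:
        mask = np.zeros(ac.size, bool)
        for t0, t1 in spans:
            mask[int(t0 * fs): int(t1 * fs)] = True
        inside = ac[mask]
        med = np.median(inside)
        mad = np.median(np.abs(inside - med))
        threshold = med + 0.5 * mad
    dist = max(int(round(min_separation_s * fs)), 1)
    pulse_times, ipis, rates = [], [], []
    for t0, t1 in spans:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = ac[i0:i1]
        if seg.size == 0:
            rates.append(0.0)
            continue
        idx, _ = sps.find_peaks(seg, height=threshold, distance=dist)
        times = (i0 + idx) / fs
        pulse_times.extend(times)
        ipis.extend(np.diff(times))
        rates.append(len(idx) / (t1 - t0))
    return {
        "pulse_times": np.asarray(pulse_times),
        "ipis": np.asarray(ipis),
        "rates_per_utterance": np.asarray(rates),
        "median_rate": float(np.median(rates)) if rates else 0.0,
        "threshold": float(threshold),
    }


def impulse_train(times_s, fs, n_samples) -> np.ndarray:
    """Unit impulse train at the given event times."""
    x = np.zeros(int(n_samples))
    idx = np.round(np.asarray(times_s, dtype=float) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    x[idx] = 1.0
    return x


def _lag_design(features, lag_samples):
    """Lag-expanded design matrix (n_samples, n_features * n_lags)."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat, n = F.shape
    cols = []
    for f in range(n_feat):
        for l in lag_samples:
            # weight at lag l multiplies feature value at t - l: the
            # response *follows* the feature for positive lags
            cols.append(np.roll(F[f], l) * _edge_mask(n, l))
    return np.column_stack(cols)


def _edge_mask(n, l):
    m = np.ones(n)
    if l > 0:
        m[:l] = 0.0
    elif l < 0:
        m[l:] = 0.0
    return m


def _blocked_folds(n, k):
    edges = np.linspace(0, n, k + 1).astype(int)
    return [(np.r_[0:edges[i], edges[i + 1]:n], np.r_[edges[i]:edges[i + 1]])
            for i in range(k)]


def _ridge_path_svd(Xtr, ytr, lambdas):
    """Ridge solutions for all lambdas from one SVD of the training design."""
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    Uty = U.T @ ytr
    ws = []
    for lam in lambdas:
        if lam == 0 and s[-1] < 1e-10 * s[0]:
            raise np.linalg.LinAlgError(
                "rank-deficient design with lambda=0; use lambda > 0")
        d = s / (s**2 + lam)
        ws.append(Vt.T @ (d * Uty))
    return ws


def fit_mtrf(features, target, fs, lags=(-0.6, 0.6), lambdas=None,
             cv_folds: int = 5, seed: int = 0, feature_names=None) -> TRFModel:
    """Time-lagged ridge ("mTRF") encoding model.

    ``features`` is (n_features, n_samples) — impulse trains or continuous
    regressors; ``target`` the per-sample series to predict.  The design is
    expanded over a symmetric lag grid spanning ``lags`` (s), ridge-solved
    in closed form, with the penalty chosen by blocked cross-validated R^2
    (contiguous folds, respecting autocorrelation).

    Returns a :class:`TRFModel` with weights reshaped (feature, lag).
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(target, dtype=float)
    if F.shape[1] != y.size:
        raise ValueError("features and target must have equal length")
    if cv_folds < 2:
        raise ValueError("need at least 2 folds")
    if lambdas is None:
        lambdas = np.logspace(-2, 6, 9)
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    l0, l1 = int(round(lags[0] * fs)), int(round(lags[1] * fs))
    lag_samples = np.arange(l0, l1 + 1)
    X = _lag_design(F, lag_samples)
    n = y.size

    folds = _blocked_folds(n, cv_folds)
    scores = np.zeros((len(lambdas), cv_folds))
    for k, (tr, te) in enumerate(folds):
        Xm, ym = X[tr].mean(axis=0), y[tr].mean()
        ws = _ridge_path_svd(X[tr] - Xm, y[tr] - ym, lambdas)
        yte = y[te]
        ss_tot = np.sum((yte - ym) ** 2)
        for i, w in enumerate(ws):
            pred = (X[te] - Xm) @ w + ym
            scores[i, k] = 1.0 - np.sum((yte - pred) ** 2) / max(ss_tot, 1e-300)
    mean_scores = scores.mean(axis=1)
    best = int(np.argmax(mean_scores))
    lam = float(lambdas[best])

    Xm, ym = X.mean(axis=0), y.mean()
    w = _ridge_path_svd(X - Xm, y - ym, [lam])[0]
    weights = w.reshape(F.shape[0], lag_samples.size)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(F.shape[0])]
    return TRFModel(lags_s=lag_samples / fs, weights=weights,
                    ridge_lambda=lam, cv_r2=float(mean_scores[best]),
                    feature_names=names, intercept=float(ym - Xm @ w))


def unique_variance(features, target, fs, feature_index: int,
                    **fit_kwargs) -> float:
    """Unique variance (delta cross-validated R^2) of one feature.

    Fits the full model and the model without the feature under the same
    fold structure and penalty-selection protocol; returns
    ``cv_r2(full) - cv_r2(reduced)``.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if not 0 <= feature_index < F.shape[0]:
        raise ValueError("feature_index not in design")
    if F.shape[0] == 1:
        raise ValueError("removing the feature would empty the design")
    full = fit_mtrf(F, target, fs, **fit_kwargs)
    reduced = fit_mtrf(np.delete(F, feature_index, axis=0), target, fs, **fit_kwargs)
    return float(full.cv_r2 - reduced.cv_r2)


def trf_response_profile(model: TRFModel, feature, prominence_frac: float = 0.2):
    """Lag-resolved weight curve of one feature, with annotated peak lags.

    Returns ``(lags_s, weights, peak_lags_s)``; peaks are local maxima with
    prominence at least ``prominence_frac`` of the curve's peak-to-peak
    range (none for a flat curve).
    """
    if isinstance(feature, str):
        if feature not in model.feature_names:
            raise ValueError(f"unknown feature {feature!r}")
        fi = model.feature_names.index(feature)
    else:
        fi = int(feature)
        if not 0 <= fi < model.weights.shape[0]:
            raise ValueError("unknown feature index")
    curve = model.weights[fi]
    ptp = np.ptp(curve)
    if ptp == 0:
        return model.lags_s, curve, np.array([])
    idx, _ = sps.find_peaks(curve, prominence=prominence_frac * ptp)
    return model.lags_s, curve, model.lags_s[idx]
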