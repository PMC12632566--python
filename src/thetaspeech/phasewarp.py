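"""Theta-trough anchoring, phase warping of epochs onto a uniform phase
axis, phase-locked averaging with surrogate bands, and phase-resolved
syllable decoding.

Warping: each epoch's unwrapped analytic theta phase is used to resample
the concurrent signals (HG amplitude, AC, any channel set) by linear
interpolation onto a common axis spanning [-9*pi, 7*pi], with the anchor
trough mapped to phase 0.  Averaging in this domain preserves alignment
with the theta cycle and avoids phase cancellation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import BandSignal, DecodingResult, PhaseAlignedEpochs
from .coupling import bh_fdr

__all__ = [
    "PHASE_AXIS_SPAN",
    "locate_anchor_trough",
    "phase_warp_epochs",
    "extract_syllable_epochs",
    "phase_locked_average",
    "sliding_phase_decoder",
    "combine_significant_bins",
]

PHASE_AXIS_SPAN = (-9 * np.pi, 7 * np.pi)


def locate_anchor_trough(theta: BandSignal, anchor_time_s: float) -> int:
    """Sample index of the theta trough nearest ``anchor_time_s``.

    Troughs are the samples where the unwrapped phase crosses pi (mod
    2*pi).  Ties between two equidistant troughs break toward the earlier
    one.  Raises if no trough lies within two cycles of the anchor.
    """
    fs = theta.fs
    n = theta.phase.size
    if not 0 <= anchor_time_s <= n / fs:
        raise ValueError("anchor outside the signal")
    u = np.unwrap(theta.phase)
    k0 = int(np.ceil((u[0] - np.pi) / (2 * np.pi)))
    k1 = int(np.floor((u[-1] - np.pi) / (2 * np.pi)))
    if k1 < k0:
        raise RuntimeError("no theta trough found in the signal")
    targets = np.pi + 2 * np.pi * np.arange(k0, k1 + 1)
    idx = np.searchsorted(u, targets)
    idx = np.clip(idx, 1, n - 1)
    frac = (targets - u[idx - 1]) / np.maximum(u[idx] - u[idx - 1], 1e-12)
    times = (idx - 1 + frac) / fs
    dist = np.abs(times - anchor_time_s)
    best = int(np.argmin(dist))  # argmin returns the first (earlier) tie
    period = 2 * np.pi / max(np.median(np.diff(u)) * fs, 1e-9)
    if dist[best] > 2 * period:
        raise RuntimeError("no theta trough within two cycles of the anchor")
    return int(round(times[best] * fs))


def _repair_phase(u, fs, max_slip_s: float = 0.05):
    """Enforce a nondecreasing unwrapped phase, repairing brief slips.

    Raises if the phase decreases over a span longer than ``max_slip_s``.
    """
    u = np.asarray(u, dtype=float)
    cm = np.maximum.accumulate(u)
    bad = u < cm - 1e-12
    if bad.any():
        # longest run of decreasing phase
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))
        longest = runs.max() if runs.size else 0
        if longest / fs > max_slip_s:
            raise RuntimeError("phase decreasing over more than 50 ms: phase slip")
    # strictly increasing for interpolation
    return cm + np.arange(u.size) * 1e-12


def phase_warp_epochs(phase_trials, signal_trials, anchor_indices, fs,
                      n_points: int = 160, axis_span=PHASE_AXIS_SPAN,
                      labels: pd.DataFrame | None = None,
                      anchor_times_s=None) -> PhaseAlignedEpochs:
    """Warp per-trial signals onto the uniform theta-phase axis.

    Parameters
    ----------
    phase_trials : list of 1-D arrays
        Per-trial *wrapped or unwrapped* theta phase (radians); unwrapped
        internally and required nondecreasing (brief slips repaired, longer
        ones raise).
    signal_trials : dict name -> list of per-trial arrays
        Each trial array is (n_samples,) or (n_channels, n_samples),
        sampled alongside the phase.
    anchor_indices : int per trial
        Sample of the anchor trough; its phase maps to axis position 0.
    n_points : int
        Number of points on the axis (default 160 = 10 per pi over 16 pi).

    Trials that do not cover the full axis are edge-flagged in ``valid``,
    never extrapolated (edge values are repeated but marked invalid).
    """
    lo, hi = axis_span
    axis = np.linspace(lo, hi, n_points)
    names = list(signal_trials)
    n_in = len(phase_trials)
    rel_phases, keep = [], []
    for t in range(n_in):
        try:
            u = _repair_phase(np.unwrap(np.asarray(phase_trials[t], dtype=float)),
                              fs)
        except RuntimeError:
            continue  # phase slip: trial dropped (logged below)
        rel_phases.append(u - u[int(anchor_indices[t])])
        keep.append(t)
    if not keep:
        raise RuntimeError("all trials dropped for phase slips")
    if len(keep) < n_in:
        warnings.warn(f"dropped {n_in - len(keep)} trials with phase slips")
    n_trials = len(keep)
    out = {}
    valid = np.zeros((n_trials, n_points), dtype=bool)
    for k, rel in enumerate(rel_phases):
        valid[k] = (axis >= rel[0]) & (axis <= rel[-1])
    for name in names:
        trials = signal_trials[name]
        first = np.atleast_2d(np.asarray(trials[keep[0]], dtype=float))
        n_ch = first.shape[0]
        arr = np.empty((n_trials, n_ch, n_points))
        for k, t in enumerate(keep):
            sig = np.atleast_2d(np.asarray(trials[t], dtype=float))
            for c in range(n_ch):
                arr[k, c] = np.interp(axis, rel_phases[k], sig[c])
        out[name] = arr[:, 0, :] if n_ch == 1 else arr
    if labels is None:
        labels = pd.DataFrame(index=range(n_in))
    labels = labels.reset_index(drop=True).iloc[keep].reset_index(drop=True)
    if anchor_times_s is None:
        anchor_times_s = np.asarray(anchor_indices, dtype=float) / fs
    anchor_times_s = np.asarray(anchor_times_s, dtype=float)[keep]
    return PhaseAlignedEpochs(phase_axis=axis, signals=out,
                              anchor_trough_time_s=anchor_times_s,
                              labels=labels, valid=valid)


def extract_syllable_epochs(theta: BandSignal, signals: dict, events,
                            fs_signals=None, pre_s: float = 0.85,
                            post_s: float = 0.75, n_points: int = 160,
                            min_quiet_s: float = 0.0, ac=None,
                            ac_threshold: float | None = None) -> PhaseAlignedEpochs:
    """Cut epochs around syllable nuclei and warp them onto the phase axis.

    ``signals`` maps names to continuous arrays (1-D, or channels x samples)
    sampled at ``theta.fs`` (or ``fs_signals[name]``, resampled by linear
    interpolation onto the LFP clock).  When ``min_quiet_s > 0`` and an
    ``ac`` series is given, only syllables preceded by at least that much
    time with AC below ``ac_threshold`` are kept (well-isolated syllables).
    """
    fs = theta.fs
    n = theta.phase.size
    syl = events.syllables
    keep_rows, ep_phase, ep_sigs, anchors, anchor_times = [], [], {k: [] for k in signals}, [], []
    resampled = {}
    for name, sig in signals.items():
        sig = np.atleast_2d(np.asarray(sig, dtype=float))
        fs_in = fs if fs_signals is None else fs_signals.get(name, fs)
        if fs_in != fs:
            t_in = np.arange(sig.shape[1]) / fs_in
            t_out = np.arange(n) / fs
            sig = np.vstack([np.interp(t_out, t_in, row) for row in sig])
        resampled[name] = sig
    if min_quiet_s > 0 and ac is not None and ac_threshold is None:
        med = np.median(ac)
        ac_threshold = med + np.median(np.abs(ac - med))
    for _, row in syl.iterrows():
        nuc = float(row.nucleus_s)
        i0 = int(round((nuc - pre_s) * fs))
        i1 = int(round((nuc + post_s) * fs))
        if i0 < 0 or i1 > n:
            continue
        if min_quiet_s > 0 and ac is not None:
            fs_ac = fs if fs_signals is None else fs_signals.get("ac", fs)
            j1 = int(round((nuc - 0.08) * fs_ac))
            j0 = int(round((nuc - 0.08 - min_quiet_s) * fs_ac))
            if j0 < 0 or np.any(np.asarray(ac)[j0:j1] > ac_threshold):
                continue
        try:
            anchor = locate_anchor_trough(theta, nuc)
        except RuntimeError:
            continue
        keep_rows.append(row)
        ep_phase.append(theta.phase[i0:i1])
        anchors.append(anchor - i0)
        anchor_times.append(anchor / fs)
        for name in signals:
            ep_sigs[name].append(resampled[name][:, i0:i1])
    if not keep_rows:
        raise ValueError("no syllables usable for epoching")
    labels = pd.DataFrame(keep_rows).reset_index(drop=True)
    return phase_warp_epochs(ep_phase, ep_sigs, anchors, fs, n_points=n_points,
                             labels=labels, anchor_times_s=anchor_times)


def phase_locked_average(epochs: PhaseAlignedEpochs, signal: str = "ac",
                         n_surrogates: int = 50, seed: int = 0,
                         min_trials: int = 20, hist_bins: int = 24) -> dict:
    """Trial-average on the phase axis with a circular-shift surrogate band.

    Surrogates shift each trial's warped trace along the phase axis by a
    random amount of at least one theta cycle (equivalent to circularly
    shifting that trial's theta phases), giving per-phase-point 2.5/97.5
    percentile bounds of the null mean.  Also returns the normalized
    histogram of per-trial peak phases (wrapped to [0, 2*pi)).
    """
    arr = np.asarray(epochs.signals[signal], dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=1)  # average channels for a population trace
    n_trials, n_points = arr.shape
    if n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    masked = np.where(epochs.valid, arr, np.nan)
    mean = np.nanmean(masked, axis=0)

    rng = np.random.default_rng(seed)
    step = epochs.phase_axis[1] - epochs.phase_axis[0]
    min_shift = max(int(np.ceil(2 * np.pi / step)), 1)
    sur_means = np.empty((n_surrogates, n_points))
    for s in range(n_surrogates):
        shifts = rng.integers(min_shift, n_points - min_shift, size=n_trials)
        rolled = np.stack([np.roll(arr[t], sh) for t, sh in enumerate(shifts)])
        sur_means[s] = rolled.mean(axis=0)
    band = np.percentile(sur_means, [2.5, 97.5], axis=0)

    peak_phases = []
    for t in range(n_trials):
        idx, _ = sps.find_peaks(arr[t], prominence=0.2 * max(np.ptp(arr[t]), 1e-12))
        peak_phases.extend(epochs.phase_axis[idx] % (2 * np.pi))
    hist, edges = np.histogram(peak_phases, bins=hist_bins, range=(0, 2 * np.pi))
    hist = hist / max(hist.sum(), 1)
    return {
        "phase_axis": epochs.phase_axis,
        "mean": mean,
        "null_band": band,
        "surrogate_means": sur_means,
        "peak_hist": hist,
        "peak_hist_edges": edges,
    }


def sliding_phase_decoder(epochs: PhaseAlignedEpochs, label_column: str = "label",
                          signal: str = "hg", window_rad: float = 0.3,
                          step_rad: float = np.pi / 4, n_shuffles: int = 50,
                          cv_folds: int = 5, min_repetitions: int = 10,
                          seed: int = 0, q: float = 0.05, C: float = 1.0,
                          phase_range=None) -> DecodingResult:
    """Sliding-window linear-SVM decoding of syllable identity by phase.

    Features per phase bin: the mean warped HG of each electrode within a
    ``window_rad`` window.  Classes with fewer than ``min_repetitions``
    trials are dropped with a warning.  Per bin, accuracy is estimated by
    stratified cross-validation (features z-scored within training folds);
    the null distribution comes from ``n_shuffles`` label permutations
    under the same folds, and bins are BH-FDR masked at level ``q``.
    """
    arr = np.asarray(epochs.signals[signal], dtype=float)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    labels_all = epochs.labels[label_column].to_numpy()
    classes, counts = np.unique(labels_all, return_counts=True)
    keep_classes = classes[counts >= min_repetitions]
    if keep_classes.size < classes.size:
        warnings.warn(f"dropped {classes.size - keep_classes.size} classes "
                      f"below {min_repetitions} repetitions")
    if keep_classes.size < 2:
        raise ValueError("need at least 2 classes with enough repetitions")
    tsel = np.isin(labels_all, keep_classes)
    arr = arr[tsel]
    y = np.searchsorted(keep_classes, labels_all[tsel])
    n_trials = y.size
    axis = epochs.phase_axis
    lo = axis[0] if phase_range is None else phase_range[0]
    hi = axis[-1] if phase_range is None else phase_range[1]
    centers = np.arange(lo + window_rad / 2, hi - window_rad / 2 + 1e-9, step_rad)

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(n_trials), y))
    perms = [rng.permutation(y) for _ in range(n_shuffles)]

    K = keep_classes.size
    acc = np.empty(centers.size)
    null_mean = np.empty(centers.size)
    null_ci = np.empty((centers.size, 2))
    pvals = np.empty(centers.size)
    scores = np.zeros((centers.size, n_trials, K))

    def _cv_accuracy(X, yy, collect=None):
        correct = 0
        for tr, te in folds:
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovr")
            clf.fit(scaler.transform(X[tr]), yy[tr])
            pred = clf.predict(scaler.transform(X[te]))
            correct += int(np.sum(pred == yy[te]))
            if collect is not None:
                df = clf.decision_function(scaler.transform(X[te]))
                if df.ndim == 1:  # binary
                    df = np.column_stack([-df, df])
                # map classifier classes back to full class set
                collect[np.ix_(te, clf.classes_)] = df
        return correct / len(yy)

    for b, c in enumerate(centers):
        sel = (axis >= c - window_rad / 2) & (axis <= c + window_rad / 2)
        if not sel.any():  # window narrower than the grid: nearest point
            sel = np.zeros_like(sel)
            sel[np.argmin(np.abs(axis - c))] = True
        X = arr[:, :, sel].mean(axis=2)
        collect = scores[b]
        acc[b] = _cv_accuracy(X, y, collect=collect)
        null = np.array([_cv_accuracy(X, p) for p in perms])
        null_mean[b] = null.mean()
        null_ci[b] = np.percentile(null, [2.5, 97.5])
        pvals[b] = (1 + int(np.sum(null >= acc[b]))) / (1 + n_shuffles)
    mask, _ = bh_fdr(pvals, q=q)
    return DecodingResult(bin_centers=centers, accuracy=acc, null_mean=null_mean,
                          null_ci=null_ci, p_values=pvals, significant_bins=mask,
                          scores=scores, labels=y, classes=keep_classes,
                          n_classes=K)


def combine_significant_bins(result: DecodingResult):
    """Combine classifier outputs across significant bins.

    Per-trial decision scores are summed across the significant phase bins
    with weights proportional to each bin's accuracy; the argmax gives the
    combined decision.  Returns a dict with combined accuracy and the
    confusion matrix, or ``{"status": "no-significant-bins"}``.
    """
    sig = np.flatnonzero(result.significant_bins)
    if sig.size == 0:
        return {"status": "no-significant-bins", "combined_accuracy": None,
                "confusion": None}
    w = result.accuracy[sig]
    w = w / w.sum()
    combined = np.tensordot(w, result.scores[sig], axes=(0, 0))
    pred = np.argmax(combined, axis=1)
    accuracy = float(np.mean(pred == result.labels))
    conf = confusion_matrix(result.labels, pred, labels=np.arange(result.n_classes))
    return {"status": "ok", "combined_accuracy": accuracy, "confusion": conf,
            "weights": w, "bins": result.bin_centers[sig]}
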