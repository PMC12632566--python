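"""Rhythm periodicity (ACF) and its relation to speaking rate; matched-trial
resampling and coupling contrasts for fluent-versus-error speech.

Periodicity of the theta-band signal is summarized by the magnitude of the
secondary autocorrelation peak: 1 for a pure sinusoid, decaying toward the
filter floor as the oscillator's bandwidth grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .circstats import (circ_mean, circ_tests, fisher_dispersion_test,
                        resultant_length, wrap)
from .containers import PeriodicityResult
from .coupling import preferred_phase, tort_mi

__all__ = [
    "acf_periodicity",
    "rate_periodicity_analysis",
    "matched_trial_resample",
    "fluency_coupling_contrast",
    "circ_tests",  # shared circular tests (implemented in circstats)
]


def acf_periodicity(sig, fs, band=(6.0, 10.0), max_lag_s: float = 0.5) -> PeriodicityResult:
    """Secondary autocorrelation peak of the band-limited signal.

    The signal is band-passed (zero-phase FIR; skipped when ``band`` is
    None), autocorrelated with the unbiased normalization, and the first
    local maximum at a lag beyond half a cycle of the band center is
    reported.  Amplitude-scaling invariant.  If no local maximum exists in
    range, periodicity 0 is returned with ``found=False``.
    """
    x = np.asarray(sig, dtype=float)
    fc = np.mean(band) if band is not None else None
    if band is not None:
        if x.size < 10 * fs / fc:
            raise ValueError("need at least 10 cycles of the band center")
        from .phasecoh import band_analytic

        bs = band_analytic(x, fs, band=band)
        # reconstruct the filtered waveform from amplitude/phase
        x = bs.amplitude * np.cos(bs.phase)
    x = x - x.mean()
    n = x.size
    max_lag = int(round(max_lag_s * fs))
    ac = np.correlate(x, x, mode="full")[n - 1: n - 1 + max_lag + 1]
    denom = (n - np.arange(max_lag + 1)) * x.var()
    ac = ac / np.maximum(denom, 1e-300)
    # the unbiased normalization can marginally exceed 1 at long lags
    ac = np.clip(ac, -1.0, 1.0)
    ac[0] = 1.0
    lags = np.arange(max_lag + 1) / fs
    start = int(round(0.5 / (fc if fc else (1.0 / max_lag_s)) * fs))
    idx, _ = sps.find_peaks(ac[start:])
    band_power = float(x.var())
    if idx.size == 0:
        return PeriodicityResult(lags_s=lags, acf=ac, secondary_peak=0.0,
                                 secondary_peak_lag_s=float("nan"),
                                 band_power=band_power, found=False)
    first = start + idx[0]
    return PeriodicityResult(lags_s=lags, acf=ac, secondary_peak=float(ac[first]),
                             secondary_peak_lag_s=float(lags[first]),
                             band_power=band_power, found=True)


def rate_periodicity_analysis(periodicity, rates, n_perm: int = 10000,
                              seed: int = 0) -> dict:
    """Median-split comparison and rank correlation of periodicity vs rate.

    Subjects are split into fast/slow speakers at the median syllable rate
    (ties assigned by stable order and flagged); groups are compared with a
    rank-sum test, and Spearman correlation is reported with a permutation
    p (useful at the small n typical of subject-level analyses) alongside
    the asymptotic one.
    """
    per = np.asarray(periodicity, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = per.size
    if n < 6:
        raise ValueError("need at least 6 subjects")
    order = np.argsort(rates, kind="stable")
    half = n // 2
    slow_idx, fast_idx = order[:half], order[half:]
    tie_at_median = np.sum(rates == np.median(rates)) > 1
    u, p_ranksum = stats.mannwhitneyu(per[fast_idx], per[slow_idx],
                                      alternative="two-sided")
    rho, p_asym = stats.spearmanr(per, rates)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r, _ = stats.spearmanr(per, rng.permutation(rates))
        if abs(r) >= abs(rho):
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return {
        "fast_idx": fast_idx, "slow_idx": slow_idx,
        "fast_median": float(np.median(per[fast_idx])),
        "slow_median": float(np.median(per[slow_idx])),
        "ranksum_p": float(p_ranksum),
        "spearman_rho": float(rho),
        "spearman_p_perm": float(p_perm),
        "spearman_p_asymptotic": float(p_asym),
        "median_tie_flag": bool(tie_at_median),
    }


def matched_trial_resample(error_trials: pd.DataFrame, fluent_trials: pd.DataFrame,
                           n_resamples: int = 200, seed: int = 0,
                           covariates=("syllable_rate", "duration_s"),
                           min_error_trials: int = 10) -> dict:
    """Fluent control sets matched to error trials in rate/duration/count.

    Each resample draws, for every error trial, the nearest unused fluent
    trial in standardized covariate space (greedy nearest neighbor without
    replacement, random visiting order), repeated ``n_resamples`` times.
    Subjects with fewer than ``min_error_trials`` error trials get
    ``excluded=True`` and no resamples.
    """
    err = error_trials.copy()
    flu = fluent_trials.copy()
    for df in (err, flu):
        if "duration_s" in covariates and "duration_s" not in df.columns:
            df["duration_s"] = df["offset_s"] - df["onset_s"]
    if len(err) < min_error_trials:
        return {"excluded": True, "n_error": len(err), "resamples": []}
    if len(flu) < len(err):
        raise ValueError("fluent pool smaller than the error set")
    E = err[list(covariates)].to_numpy(dtype=float)
    F = flu[list(covariates)].to_numpy(dtype=float)
    pooled_sd = np.vstack([E, F]).std(axis=0)
    pooled_sd[pooled_sd == 0] = 1.0
    Es, Fs = E / pooled_sd, F / pooled_sd
    rng = np.random.default_rng(seed)
    resamples, medians = [], []
    for _ in range(n_resamples):
        used = np.zeros(len(flu), dtype=bool)
        pick = np.empty(len(err), dtype=int)
        for k in rng.permutation(len(err)):
            d = np.linalg.norm(Fs - Es[k], axis=1)
            d[used] = np.inf
            j = int(np.argmin(d))
            used[j] = True
            pick[k] = j
        resamples.append(flu.index.to_numpy()[pick])
        medians.append(np.median(F[pick], axis=0))
    medians = np.asarray(medians)
    return {
        "excluded": False,
        "n_error": len(err),
        "n_resamples": n_resamples,
        "resamples": resamples,
        "matched_covariate_medians": medians.mean(axis=0),
        "error_covariate_medians": np.median(E, axis=0),
        "covariates": list(covariates),
    }


def fluency_coupling_contrast(per_electrode, fluent_mask, n_bins: int = 24,
                              seed: int = 0) -> dict:
    """Theta-movement coupling contrast between fluent and error trials.

    ``per_electrode`` is a list over electrodes; each element is
    ``(trial_phases, trial_ac)``, lists over trials of the per-sample theta
    phase and AC series.  ``fluent_mask`` flags fluent trials (shared trial
    order across electrodes).

    Per electrode, the Tort MI and preferred phase are computed separately
    over pooled fluent and pooled error samples; the contrast reports the
    MI reduction (with a Wilcoxon signed-rank p across electrodes), the
    across-electrode resultant length of fluent-vs-error preferred-phase
    differences against the fluent odd/even split-half consistency, and
    Fisher's dispersion test between the two sets of phase differences.
    """
    fluent_mask = np.asarray(fluent_mask, dtype=bool)
    mi_f, mi_e, dphi_fe, dphi_oe = [], [], [], []
    dropped = 0
    fl_idx = np.flatnonzero(fluent_mask)
    for phases, acs in per_electrode:
        def _pool(idx):
            ph = np.concatenate([np.asarray(phases[i], float) for i in idx])
            mg = np.concatenate([np.asarray(acs[i], float) for i in idx])
            return ph, mg

        try:
            ph_f, ac_f = _pool(np.flatnonzero(fluent_mask))
            ph_e, ac_e = _pool(np.flatnonzero(~fluent_mask))
            rf = tort_mi(ph_f, ac_f, n_bins=n_bins)
            re_ = tort_mi(ph_e, ac_e, n_bins=n_bins)
            ph_o, ac_o = _pool(fl_idx[::2])
            ph_v, ac_v = _pool(fl_idx[1::2])
            ro = tort_mi(ph_o, ac_o, n_bins=n_bins)
            rv = tort_mi(ph_v, ac_v, n_bins=n_bins)
            pf, pe = rf.preferred_phase, re_.preferred_phase
            po, pv = ro.preferred_phase, rv.preferred_phase
            if any(np.isnan(v) for v in (pf, pe, po, pv)):
                raise ValueError("undefined preferred phase")
        except ValueError:
            dropped += 1
            continue
        mi_f.append(rf.mi)
        mi_e.append(re_.mi)
        dphi_fe.append(wrap(pf - pe))
        dphi_oe.append(wrap(po - pv))
    mi_f, mi_e = np.asarray(mi_f), np.asarray(mi_e)
    if mi_f.size == 0:
        raise ValueError("no electrodes with defined coupling in both groups")
    if mi_f.size >= 6 and np.any(mi_f != mi_e):
        _, p_mi = stats.wilcoxon(mi_f, mi_e, alternative="greater")
    else:
        p_mi = 1.0 if np.all(mi_f == mi_e) else float("nan")
    consistency_fluent = float(resultant_length(dphi_oe))
    consistency_error = float(resultant_length(dphi_fe))
    if mi_f.size >= 5:
        fstat, p_disp = fisher_dispersion_test(dphi_oe, dphi_fe, seed=seed)
    else:
        fstat, p_disp = float("nan"), float("nan")
    return {
        "mi_fluent": mi_f,
        "mi_error": mi_e,
        "mi_difference": float(np.mean(mi_f - mi_e)),
        "mi_p": float(p_mi),
        "consistency_fluent": consistency_fluent,
        "consistency_error": consistency_error,
        "dispersion_stat": fstat,
        "dispersion_p": float(p_disp),
        "n_electrodes": int(mi_f.size),
        "n_dropped": dropped,
    }
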