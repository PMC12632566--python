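"""Phase-magnitude coupling via Tort's Modulation Index, with circular-shift
surrogate inference and Benjamini-Hochberg FDR control.

The magnitude series can be anything nonnegative sampled alongside the
phase: high-gamma amplitude (classical PAC) or articulatory change (AC,
theta-movement coupling).  The profile uses 24 bins of 15 deg spanning
[0, 2pi) for both.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .circstats import circ_mean
from .containers import CouplingResult

__all__ = [
    "tort_mi",
    "preferred_phase",
    "circular_shift_surrogates",
    "bh_fdr",
]

N_BINS_DEFAULT = 24


def _bin_indices(phase, n_bins):
    ph = np.asarray(phase, dtype=float) % (2 * np.pi)
    idx = np.floor(ph / (2 * np.pi) * n_bins).astype(np.intp)
    return np.minimum(idx, n_bins - 1)


def _profile_from_bins(bins, magnitude, n_bins):
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        empty = int(np.argmin(counts))
        raise ValueError(f"phase bin {empty} is empty: insufficient data")
    sums = np.bincount(bins, weights=magnitude, minlength=n_bins)
    prof = sums / counts
    total = prof.sum()
    if total <= 0:
        return np.full(n_bins, 1.0 / n_bins)
    return prof / total


def _mi_from_profile(prof):
    n = prof.size
    nz = prof > 0
    kl = np.log(n) + np.sum(prof[nz] * np.log(prof[nz]))
    return float(kl / np.log(n))


def tort_mi(phase, magnitude, n_bins: int = N_BINS_DEFAULT) -> CouplingResult:
    """Tort modulation index of a magnitude series over phase bins.

    The mean magnitude per phase bin is normalized to a distribution P and
    MI = KL(P || uniform) / log(n_bins), in [0, 1]: 0 for a flat profile,
    1 when all magnitude concentrates in one bin.
    """
    phase = np.asarray(phase, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    if phase.shape != magnitude.shape:
        raise ValueError("phase and magnitude must have equal length")
    if (magnitude < 0).any():
        raise ValueError("magnitude must be nonnegative")
    bins = _bin_indices(phase, n_bins)
    prof = _profile_from_bins(bins, magnitude, n_bins)
    mi = _mi_from_profile(prof)
    pref = preferred_phase(prof) if not np.allclose(prof, prof[0]) else float("nan")
    return CouplingResult(mi=mi, profile=prof, preferred_phase=pref,
                          bin_width_deg=360.0 / n_bins)


def preferred_phase(profile) -> float:
    """Circular mean of bin centers weighted by the phase-binned profile.

    Radians in [0, 2pi).  Raises on an exactly uniform profile (undefined).
    """
    prof = np.asarray(profile, dtype=float)
    n = prof.size
    centers = (np.arange(n) + 0.5) * 2 * np.pi / n
    z = np.sum(prof * np.exp(1j * centers))
    if np.abs(z) / max(prof.sum(), 1e-300) < 1e-12:
        raise ValueError("uniform profile: preferred phase undefined")
    return float(np.angle(z) % (2 * np.pi))


def circular_shift_surrogates(phase, magnitude, fs, n_surrogates: int = 1000,
                              min_shift_s: float = 1.0, seed: int = 0,
                              n_bins: int = N_BINS_DEFAULT,
                              mask=None) -> CouplingResult:
    """Surrogate test of phase-magnitude coupling by circular phase shifts.

    The phase series is circularly shifted by amounts drawn uniformly
    outside ``+/- min_shift_s`` (preserving its autocorrelation while
    destroying the alignment with the magnitude) and the MI recomputed per
    shift.  ``mask`` (optional, e.g. speech samples) is applied after the
    shift.  p = (1 + #{surrogate MI >= observed}) / (1 + n_surrogates).
    """
    phase = np.asarray(phase, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    n = phase.size
    if n_surrogates < 50:
        raise ValueError("n_surrogates must be >= 50")
    dur = n / fs
    if min_shift_s >= dur / 2:
        raise ValueError("min_shift_s must be < duration/2")
    if n < 4 * min_shift_s * fs:
        raise ValueError("series shorter than 4 * min_shift_s")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    bins = _bin_indices(phase, n_bins)
    obs = _mi_from_profile(_profile_from_bins(bins[mask], magnitude[mask], n_bins))
    obs_prof = _profile_from_bins(bins[mask], magnitude[mask], n_bins)

    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * fs))
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    sur = np.empty(n_surrogates)
    mag_m = magnitude[mask]
    for i, s in enumerate(shifts):
        rb = np.roll(bins, s)[mask]
        sur[i] = _mi_from_profile(_profile_from_bins(rb, mag_m, n_bins))
    p = (1 + int(np.sum(sur >= obs))) / (1 + n_surrogates)
    pref = preferred_phase(obs_prof)
    return CouplingResult(mi=obs, profile=obs_prof, preferred_phase=pref,
                          p_value=float(p), n_surrogates=n_surrogates,
                          surrogate_mi=sur, bin_width_deg=360.0 / n_bins)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(mask, adjusted)``; empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    mask, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return mask, adj
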