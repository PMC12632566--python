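"""Relating each electrode's peri-AC activation latency to its theta phase:
cross-correlogram latencies, circular-linear correlation, pairwise
lag-phase correlation, and a state-space trajectory summary.

The picture being tested: electrodes whose theta phase leads (relative to
the most ventral sensorimotor reference) should also activate earlier
around articulatory-change pulses, so phase order mirrors temporal order.
"""

from __future__ import annotations

import warnings

import numpy as np

from .circstats import circ_linear_corr, circ_mean, wrap

__all__ = [
    "xcorr_latency",
    "circ_linear_corr",  # re-exported: the estimator lives in circstats
    "pairwise_lag_phase_corr",
    "activation_state_space",
    "most_ventral_reference",
]


def most_ventral_reference(coords_mm) -> int:
    """Index of the most ventral electrode (smallest z coordinate)."""
    coords = np.asarray(coords_mm, dtype=float)
    return int(np.argmin(coords[:, 2]))


def xcorr_latency(profile, reference_profile, dt_s, max_lag_s: float = 0.3) -> float:
    """Relative latency of a response profile vs a reference profile.

    The latency is the lag (s) maximizing the normalized cross-correlation
    within ``+/- max_lag_s``; ties break toward the smallest absolute lag.
    Both profiles share the lag grid with step ``dt_s``.
    """
    a = np.asarray(profile, dtype=float)
    b = np.asarray(reference_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the lag grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("flat profile: latency undefined")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    full = np.correlate(a, b, mode="full") / a.size
    lags = (np.arange(full.size) - (a.size - 1)) * dt_s
    sel = np.abs(lags) <= max_lag_s
    full, lags = full[sel], lags[sel]
    best = full.max()
    ties = np.flatnonzero(full >= best - 1e-12)
    return float(lags[ties[np.argmin(np.abs(lags[ties]))]])


def pairwise_lag_phase_corr(latencies, phases, n_perm: int = 1000, seed: int = 0):
    """Correlation between pairwise latency and theta-phase differences.

    Over all unordered electrode pairs, the correlation between
    ``latency_i - latency_j`` and the wrapped phase difference
    ``wrap(phase_i - phase_j)`` (radians, in (-pi, pi]).  Both differences
    are antisymmetric under pair orientation, so the correlation is
    computed through the origin — this makes the result invariant to the
    arbitrary ordering convention of each pair.  Pairs are dependent, so
    significance comes from permuting electrode labels (phases relative to
    latencies); the p-value is one-sided for the observed sign of r.
    """
    lat = np.asarray(latencies, dtype=float).ravel()
    phi = np.asarray(phases, dtype=float).ravel()
    n = lat.size
    if n < 3:
        raise ValueError("need at least 3 electrodes")
    iu, ju = np.triu_indices(n, k=1)

    def _r(phi):
        dlat = lat[iu] - lat[ju]
        dphi = wrap(phi[iu] - phi[ju])
        denom = np.sqrt(np.sum(dlat**2) * np.sum(dphi**2))
        return np.sum(dlat * dphi) / max(denom, 1e-300)

    obs = _r(phi)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = _r(rng.permutation(phi))
        if (r >= obs) if obs >= 0 else (r <= obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)


def activation_state_space(profiles, phases, top_fraction: float = 0.10):
    """State-space trajectory of peri-AC activation with phase coloring.

    ``profiles`` is (n_electrodes, n_lags).  The lag-by-lag activation
    pattern is projected onto its first two principal components (electrode
    loadings); at each lag the circular mean theta phase of the
    ``top_fraction`` most active electrodes (by magnitude of the rank-2
    reconstruction) is reported.

    Returns a dict with the 2-D ``trajectory`` (n_lags, 2), per-lag
    ``phase_color`` (radians), explained-variance ratios and the electrode
    loadings.
    """
    P = np.asarray(profiles, dtype=float)
    phi = np.asarray(phases, dtype=float).ravel()
    n_el, n_lags = P.shape
    if n_el < 3 or n_lags < 3:
        raise ValueError("need at least 3 electrodes and 3 lags")
    X = P.T - P.T.mean(axis=0)  # (n_lags, n_electrodes), centered per electrode
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * s[0]))
    if rank < 2:
        warnings.warn("profiles have rank < 2: reduced-dimension trajectory")
    n_comp = min(2, rank) or 1
    trajectory = U[:, :n_comp] * s[:n_comp]
    loadings = Vt[:n_comp]
    recon = trajectory @ loadings  # (n_lags, n_electrodes), rank-2 activation
    k = int(np.ceil(top_fraction * n_el))
    phase_color = np.empty(n_lags)
    for t in range(n_lags):
        top = np.argsort(np.abs(recon[t]))[::-1][:k]
        phase_color[t] = circ_mean(phi[top])
    evr = (s**2) / np.sum(s**2)
    return {
        "trajectory": trajectory,
        "phase_color": phase_color,
        "explained_variance_ratio": evr[:n_comp],
        "loadings": loadings,
        "n_top": k,
    }
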