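"""Circular statistics used throughout the pipeline.

Angles are radians.  Functions accept any array-like; NaNs are not handled
(callers filter first).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "wrap",
    "circ_mean",
    "resultant_length",
    "rayleigh_test",
    "watson_u2",
    "circ_linear_corr",
    "fisher_dispersion_test",
    "circ_tests",
]


def wrap(angles):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + np.pi) % (2 * np.pi) - np.pi)


def circ_mean(angles, weights=None, axis=None):
    """Weighted circular mean direction in (-pi, pi]."""
    a = np.asarray(angles, dtype=float)
    if weights is None:
        z = np.exp(1j * a).sum(axis=axis)
    else:
        z = (np.asarray(weights, dtype=float) * np.exp(1j * a)).sum(axis=axis)
    return np.angle(z)


def resultant_length(angles, weights=None, axis=None):
    """Mean resultant length (MRL) in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if weights is None:
        return np.abs(np.exp(1j * a).mean(axis=axis))
    w = np.asarray(weights, dtype=float)
    return np.abs((w * np.exp(1j * a)).sum(axis=axis)) / w.sum(axis=axis)


def rayleigh_test(angles):
    """Rayleigh test of circular uniformity.

    Returns (mrl, p).  Uses the standard finite-n approximation of the
    p-value (accurate for n >= 5).
    """
    a = np.asarray(angles, dtype=float).ravel()
    n = a.size
    if n < 5:
        raise ValueError("rayleigh_test needs n >= 5")
    r = resultant_length(a)
    R = n * r
    z = R**2 / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(r), float(min(max(p, np.finfo(float).tiny), 1.0))


def _watson_u2_stat(a, b):
    """Two-sample Watson U^2 statistic (ties broken by ordering)."""
    n, m = len(a), len(b)
    N = n + m
    allv = np.concatenate([a, b])
    order = np.argsort(allv, kind="mergesort")
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])[order]
    # cumulative empirical CDF difference at each ordered point
    da = np.cumsum(is_a) / n
    db = np.cumsum(~is_a) / m
    dk = da - db
    return (n * m) / N**2 * (np.sum(dk**2) - np.sum(dk) ** 2 / N)


def watson_u2(angles1, angles2, n_perm: int = 1000, seed: int = 0):
    """Two-sample Watson U^2 test of common distribution on the circle.

    The statistic is rotation-invariant; significance by permutation of
    group labels.  Returns (u2, p).
    """
    a = wrap(np.asarray(angles1, float).ravel()) % (2 * np.pi)
    b = wrap(np.asarray(angles2, float).ravel()) % (2 * np.pi)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("watson_u2 needs n >= 5 per sample")
    obs = _watson_u2_stat(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(perm[:n], perm[n:]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)


def circ_linear_corr(phases, x, n_perm: int = 1000, seed: int = 0):
    """Circular-linear correlation between angles and a linear variable.

    rho is the multiple correlation of x on (cos phi, sin phi):

        rho^2 = (r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)

    Returns (rho, p_perm, p_asymptotic); the asymptotic p uses
    n * rho^2 ~ chi^2(2) under independence.
    """
    phi = np.asarray(phases, float).ravel()
    x = np.asarray(x, float).ravel()
    n = phi.size
    if n < 6:
        raise ValueError("circ_linear_corr needs n >= 6")
    if not np.all(np.isfinite(x)):
        raise ValueError("latencies must be finite")
    if np.var(x) == 0:
        raise ValueError("linear variable has zero variance")

    def _rho(phi, x):
        c, s = np.cos(phi), np.sin(phi)
        rcx = np.corrcoef(c, x)[0, 1]
        rsx = np.corrcoef(s, x)[0, 1]
        rcs = np.corrcoef(c, s)[0, 1]
        num = rcx**2 + rsx**2 - 2 * rcx * rsx * rcs
        return np.sqrt(max(num / (1 - rcs**2), 0.0))

    rho = _rho(phi, x)
    p_asym = float(stats.chi2.sf(n * rho**2, df=2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _rho(phi, rng.permutation(x)) >= rho:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return float(rho), float(p_perm), p_asym


def fisher_dispersion_test(angles1, angles2, n_perm: int = 2000, seed: int = 0):
    """Two-sample test for a common circular concentration (Fisher 1993).

    Each sample is centred on its own mean direction and dispersion is
    measured as d = |sin(theta - mean)|.  The statistic is the ratio of the
    two mean dispersions; significance by permutation of group labels
    (two-sided), which stays valid at any concentration.

    Returns (statistic, p).
    """
    a = np.asarray(angles1, float).ravel()
    b = np.asarray(angles2, float).ravel()
    if len(a) < 5 or len(b) < 5:
        raise ValueError("fisher_dispersion_test needs n >= 5 per sample")

    def _disp(x):
        return np.abs(np.sin(x - circ_mean(x))).mean()

    def _stat(a, b):
        da, db = _disp(a), _disp(b)
        lo = min(da, db)
        return (max(da, db) + 1e-12) / (lo + 1e-12)

    obs = _stat(a, b)
    pooled = np.concatenate([a, b])
    n = len(a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _stat(perm[:n], perm[n:]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)


def circ_tests(angles, angles2=None, n_perm: int = 1000, seed: int = 0):
    """Bundle of circular tests shared across modules.

    Returns a dict with the mean resultant length and Rayleigh uniformity p
    of ``angles``; if ``angles2`` is given, adds the two-sample Watson U^2
    statistic and its permutation p.
    """
    a = np.asarray(angles, float).ravel()
    if a.size < 5:
        raise ValueError("circ_tests needs n >= 5")
    mrl, p_ray = rayleigh_test(a)
    out = {"mrl": mrl, "rayleigh_p": p_ray, "mean_direction": float(circ_mean(a))}
    if angles2 is not None:
        u2, p_u2 = watson_u2(a, angles2, n_perm=n_perm, seed=seed)
        out["watson_u2"] = u2
        out["watson_p"] = p_u2
    return out
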