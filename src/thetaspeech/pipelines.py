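"""Session-level conveniences tying the analysis modules together.

These helpers run the standard end-to-end recipes on a (synthetic or real)
session: extract theta phase and high-gamma amplitude, bring the
articulatory-change series onto the LFP clock, and summarize the coupling
of one site.
"""

from __future__ import annotations

import numpy as np

from . import coupling, kinematics, phasecoh
from .containers import BandSignal
from .synthgen import SyntheticSession

__all__ = [
    "THETA_BAND",
    "HG_BAND",
    "theta_phase",
    "hg_amplitude",
    "ac_on_lfp_clock",
    "site_coupling_summary",
]

THETA_BAND = (6.0, 10.0)
HG_BAND = (70.0, 150.0)


def theta_phase(session: SyntheticSession, channel: int = 0,
                band=THETA_BAND) -> BandSignal:
    """Theta-band analytic signal of one recording channel."""
    return phasecoh.band_analytic(session.recording.data[channel],
                                  session.recording.fs, band)


def hg_amplitude(session: SyntheticSession, channel: int = 0,
                 band=HG_BAND) -> np.ndarray:
    """High-gamma analytic amplitude of one recording channel."""
    return phasecoh.band_analytic(session.recording.data[channel],
                                  session.recording.fs, band).amplitude


def ac_on_lfp_clock(session: SyntheticSession, **ac_kwargs) -> np.ndarray:
    """Articulatory change, linearly resampled onto the LFP sample clock."""
    ac = kinematics.articulatory_change(session.kinematics, **ac_kwargs)
    t_lfp = np.arange(session.recording.n_samples) / session.recording.fs
    return np.interp(t_lfp, session.kinematics.times, ac)


def site_coupling_summary(session: SyntheticSession, channel: int = 0,
                          n_surrogates: int = 200, seed: int = 0,
                          speech_only: bool = True) -> dict:
    """Theta/HG and theta/AC coupling of one site, with surrogate p-values.

    Returns preferred phases (radians in [0, 2pi)), modulation indices,
    p-values and the AC-vs-HG preferred-phase offset for the given channel.
    """
    fs = session.recording.fs
    bs = theta_phase(session, channel)
    hg = hg_amplitude(session, channel)
    ac = ac_on_lfp_clock(session)
    mask = None
    if speech_only:
        mask = session.events.speech_mask(fs, session.recording.n_samples)
    r_hg = coupling.circular_shift_surrogates(bs.phase, hg, fs,
                                              n_surrogates=n_surrogates,
                                              seed=seed, mask=mask)
    r_ac = coupling.circular_shift_surrogates(bs.phase, ac, fs,
                                              n_surrogates=n_surrogates,
                                              seed=seed + 1, mask=mask)
    offset = (r_ac.preferred_phase - r_hg.preferred_phase) % (2 * np.pi)
    return {
        "hg": r_hg,
        "ac": r_ac,
        "hg_preferred_phase": r_hg.preferred_phase,
        "ac_preferred_phase": r_ac.preferred_phase,
        "ac_minus_hg_deg": float(np.degrees(offset)),
    }
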