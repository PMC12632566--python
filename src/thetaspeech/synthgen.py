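"""Synthetic ECoG + articulatory-kinematics sessions.

Generates multichannel field potentials, vocal-tract trajectories and
time-aligned annotations with the statistical structure the analysis
pipeline assumes:

* a stable-frequency theta oscillator (default 8.2 Hz) riding on a 1/f
  aperiodic background, shared across channels with per-channel phase
  offsets (a near-zero majority plus an antiphase subset, optionally a
  dorsoventral phase gradient);
* high-gamma (HG) band-limited noise whose envelope is modulated by the
  local theta phase (phase-amplitude coupling), maximal near the trough;
* gesture velocity pulses in six tract variables, locked to a late theta
  phase (default 301 deg), organized as onset-nucleus-coda triplets around
  each syllable with occasional skipped cycles;
* error trials whose theta-movement coupling is degraded by phase jitter.

Phase convention throughout: 0 = waveform positive peak, pi = trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import EventTable, Recording, TractKinematics

__all__ = [
    "SessionConfig",
    "SyntheticSession",
    "TRACT_VARIABLES",
    "SYLLABLE_INVENTORY",
    "theta_carrier",
    "analytic_theta_carrier",
    "aperiodic_noise",
    "pac_envelope_signal",
    "gesture_pulse_kinematics",
    "make_session",
]

#: The six measured tract variables.
TRACT_VARIABLES = [
    "lip_aperture",
    "lip_protrusion",
    "tongue_tip",
    "tongue_body",
    "tongue_root",
    "jaw",
]

#: Twelve common CV-style syllables used as decoding classes.
SYLLABLE_INVENTORY = [
    "ri", "iz", "for", "li", "ju", "da", "ne", "su", "ka", "mo", "ti", "wa",
]


@dataclass
class SessionConfig:
    """Parameters of a synthetic session.

    Defaults are the study conditions the generator emulates: an 8.2 Hz
    theta rhythm, HG amplitude maximal 208 deg into the cycle (28 deg after
    the trough, which puts the articulatory preferred phase 93 deg later at
    301 deg), gesture triplets spaced 0.125 s, and kinematics sampled at
    100 Hz.
    """

    n_channels: int = 16
    fs_lfp: float = 1000.0
    fs_kin: float = 100.0
    duration_s: float = 60.0
    theta_f0: float = 8.2
    theta_bandwidth: float = 1.5
    aperiodic_exponent: float = 1.5
    channel_phase_offsets: np.ndarray | None = None
    antiphase_fraction: float = 0.2
    phase_offset_jitter_sd: float = 0.15  # rad, within-class scatter
    phase_gradient_rad_per_mm: float = 0.0  # dorsoventral gradient, optional
    pac_depth: float = 0.4
    pac_phase: float = np.deg2rad(208.0)
    hg_band: tuple = (70.0, 150.0)
    ac_preferred_phase: float = np.deg2rad(301.0)
    cycle_skip_prob: float = 0.11
    syllable_rate: float = 4.0
    triplet_spacing_s: float = 0.125
    error_trial_fraction: float = 0.15
    error_phase_jitter_sd: float = np.deg2rad(60.0)
    coherence_modulated: bool = True  # inter-site locking only during speech
    coherence_lead_s: float = 0.2  # locking begins this long before onset
    syllable_code_strength: float = 0.6
    background_gesture_amplitude: float = 0.7  # non-triplet cycles; 0 = off
    theta_amplitude: float = 1.5
    background_amplitude: float = 1.0
    hg_amplitude: float = 0.6
    utterance_duration_s: float = 2.0
    gap_duration_s: float = 1.0
    electrode_spacing_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fs_lfp", "fs_kin", "theta_f0", "syllable_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "antiphase_fraction",
            "pac_depth",
            "cycle_skip_prob",
            "error_trial_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("pac_phase", "ac_preferred_phase"):
            setattr(self, name, float(getattr(self, name)) % (2 * np.pi))
        if self.theta_bandwidth >= self.theta_f0:
            raise ValueError("theta_bandwidth must be < theta_f0")
        if self.duration_s < 2:
            raise ValueError("duration_s must be >= 2 s")
        for fs in (self.fs_lfp, self.fs_kin):
            n = self.duration_s * fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError("duration_s * fs must be an integral sample count")

    @property
    def expected_pulse_rate(self) -> float:
        """Gesture-pulse rate implied by the cycle scheduling (pulses/s)."""
        return self.theta_f0 * (1.0 - self.cycle_skip_prob)

    def replace(self, **kw) -> "SessionConfig":
        return replace(self, **kw)


@dataclass
class SyntheticSession:
    recording: Recording
    kinematics: TractKinematics
    events: EventTable
    ground_truth: dict = field(default_factory=dict)
    config: SessionConfig | None = None


# --------------------------------------------------------------------------
# elementary signal generators
# --------------------------------------------------------------------------

def analytic_theta_carrier(fs, duration_s, f0, bandwidth, seed):
    """Complex analytic narrowband oscillator (see :func:`theta_carrier`)."""
    if fs <= 0 or f0 <= 0:
        raise ValueError("fs and f0 must be positive")
    if bandwidth < 0 or bandwidth >= f0:
        raise ValueError("bandwidth must be in [0, f0)")
    if duration_s < 2:
        raise ValueError("duration_s must be >= 2 s")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if bandwidth < 1e-9:
        phi0 = rng.uniform(0, 2 * np.pi)
        return np.exp(1j * (2 * np.pi * f0 * t + phi0))  # unit-amplitude phasor
    # Gaussian spectral envelope around f0, positive frequencies only
    x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    freqs = np.fft.fftfreq(n, 1 / fs)
    sigma = bandwidth / 2.355  # FWHM -> SD
    h = np.exp(-0.5 * ((freqs - f0) / sigma) ** 2)
    h[freqs <= 0] = 0.0
    z = np.fft.ifft(np.fft.fft(x) * h)
    return z / z.real.std()


def theta_carrier(fs, duration_s, f0, bandwidth, seed):
    """Narrowband stochastic theta oscillator.

    Gaussian noise shaped by a Gaussian spectral envelope centred on ``f0``
    with FWHM ``bandwidth``; ``bandwidth -> 0`` degenerates to a pure
    sinusoid (random starting phase).  The bandwidth controls how periodic
    the autocorrelation is: narrower band, larger secondary ACF peak.

    Returns a zero-mean waveform with unit variance of its real part.
    """
    z = analytic_theta_carrier(fs, duration_s, f0, bandwidth, seed)
    x = z.real.copy()
    if bandwidth < 1e-9:
        # cos has SD 1/sqrt(2); rescale to unit SD, keep zero mean
        x *= np.sqrt(2.0)
    return x - x.mean()


def aperiodic_noise(fs, n_samples, exponent, seed):
    """1/f^exponent background noise, zero mean, unit SD."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    y = np.fft.irfft(np.fft.rfft(x) * shaping, n_samples)
    return (y - y.mean()) / y.std()


def pac_envelope_signal(theta_phase, coupling_phase, depth, hg_band, fs, seed):
    """Band-limited noise whose envelope follows the theta phase.

    The output is high-gamma-band noise multiplied by
    ``1 + depth * cos(theta_phase - coupling_phase)``; with ``depth = 0``
    the envelope is statistically unmodulated.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    lo, hi = hg_band
    if not (0 < lo < hi):
        raise ValueError("hg_band must satisfy 0 < low < high")
    if hi >= fs / 2:
        raise ValueError("hg_band must lie below the Nyquist frequency")
    theta_phase = np.asarray(theta_phase, dtype=float)
    n = theta_phase.size
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = ((freqs >= lo) & (freqs <= hi)).astype(float)
    noise = np.fft.irfft(np.fft.rfft(x) * mask, n)
    noise /= noise.std()
    return noise * (1.0 + depth * np.cos(theta_phase - coupling_phase))


# --------------------------------------------------------------------------
# gesture kinematics
# --------------------------------------------------------------------------

def _cycle_event_times(unwrapped_phase, fs, target_phase):
    """Times at which the (unwrapped) phase passes target_phase + 2*pi*k."""
    u = np.asarray(unwrapped_phase, dtype=float)
    k0 = int(np.ceil((u[0] - target_phase) / (2 * np.pi)))
    k1 = int(np.floor((u[-1] - target_phase) / (2 * np.pi)))
    if k1 < k0:
        return np.array([]), np.array([], dtype=int)
    targets = target_phase + 2 * np.pi * np.arange(k0, k1 + 1)
    idx = np.searchsorted(u, targets)
    idx = np.clip(idx, 1, len(u) - 1)
    # linear interpolation between the bracketing samples
    frac = (targets - u[idx - 1]) / np.maximum(u[idx] - u[idx - 1], 1e-12)
    times = (idx - 1 + frac) / fs
    return times, np.arange(k0, k1 + 1)


def gesture_pulse_kinematics(theta_phase, cfg: SessionConfig, syllable_plan: EventTable,
                             seed, fs_phase=None):
    """Tract-variable trajectories with theta-locked gesture pulses.

    ``theta_phase`` is the *unwrapped* theta phase of the reference site at
    ``fs_phase`` (default ``cfg.fs_lfp``).  For each syllable, gesture
    pulses are scheduled on the theta cycles nearest the nucleus and
    nucleus +/- triplet spacing, at the phase ``cfg.ac_preferred_phase`` of
    each cycle; each scheduled cycle is skipped with probability
    ``cfg.cycle_skip_prob``.  Pulses of non-fluent utterances are jittered
    in phase by ``cfg.error_phase_jitter_sd``.  Velocity pulses are
    Gaussian bumps (sigma 20 ms) in 2-4 randomly chosen tract variables.

    Returns ``(TractKinematics, info)`` where ``info`` records pulse times,
    scheduled/skipped cycles and per-pulse amplitudes (ground truth).
    """
    fs_phase = cfg.fs_lfp if fs_phase is None else fs_phase
    rng = np.random.default_rng(seed)
    n_kin = int(round(len(theta_phase) / fs_phase * cfg.fs_kin))
    t_kin = np.arange(n_kin) / cfg.fs_kin
    syl = syllable_plan.syllables
    if len(syl) == 0:
        warnings.warn("empty syllable plan: returning zero kinematics")
        data = np.zeros((len(TRACT_VARIABLES), n_kin))
        return TractKinematics(data, cfg.fs_kin, list(TRACT_VARIABLES)), {
            "pulse_times": np.array([]), "skipped_cycles": np.array([], int)}
    dur = len(theta_phase) / fs_phase
    if (syl["nucleus_s"] < 0).any() or (syl["nucleus_s"] > dur).any():
        raise ValueError("syllable plan events outside the session duration")

    cyc_times, cyc_idx = _cycle_event_times(theta_phase, fs_phase, cfg.ac_preferred_phase)
    utt = syllable_plan.utterances
    fluent = utt["fluent"] if "fluent" in utt.columns else pd.Series(True, index=utt.index)

    # schedule: every theta cycle inside an utterance carries a gesture;
    # amplitude is graded by proximity to the syllable's nucleus (1.0) and
    # its flanking onset/coda targets (0.8), 0.7 elsewhere in the span
    scheduled = {}
    delta = cfg.triplet_spacing_s
    base_amp = cfg.background_gesture_amplitude
    for ui, urow in utt.iterrows():
        is_fluent = bool(fluent.loc[ui]) if ui in fluent.index else True
        in_span = np.flatnonzero((cyc_times >= urow.onset_s) & (cyc_times < urow.offset_s))
        for j in in_span:
            scheduled[int(j)] = (base_amp, is_fluent)
    # realized (cycle-snapped) onset/nucleus/coda times per syllable — the
    # times a forced alignment of the produced speech would report
    realized = np.full((len(syl), 3), np.nan)
    utt_fluent = {ui: (bool(fluent.loc[ui]) if ui in fluent.index else True)
                  for ui in utt.index}
    for si, (_, row) in enumerate(syl.iterrows()):
        if len(cyc_times) == 0:
            continue
        for ti, (target, amp) in enumerate((
                (row.nucleus_s - delta, 0.8), (row.nucleus_s, 1.0),
                (row.nucleus_s + delta, 0.8))):
            j = int(np.argmin(np.abs(cyc_times - target)))
            if abs(cyc_times[j] - target) > 0.5 / cfg.theta_f0:
                continue
            realized[si, ti] = cyc_times[j]
            is_fluent = utt_fluent.get(int(row["utterance"]), True) \
                if "utterance" in syl.columns else True
            if j in scheduled:
                prev_amp, prev_fluent = scheduled[j]
                scheduled[j] = (max(prev_amp, amp), prev_fluent)
            else:
                scheduled[j] = (amp, is_fluent)

    pulse_times, pulse_amps, skipped, skipped_times = [], [], [], []
    for j in sorted(scheduled):
        amp, is_fluent = scheduled[j]
        if rng.random() < cfg.cycle_skip_prob:
            skipped.append(cyc_idx[j])
            skipped_times.append(cyc_times[j])
            continue
        t = cyc_times[j]
        if not is_fluent and cfg.error_phase_jitter_sd > 0:
            t += rng.normal(0, cfg.error_phase_jitter_sd) / (2 * np.pi * cfg.theta_f0)
        if 0 <= t < dur:
            pulse_times.append(t)
            pulse_amps.append(amp)

    sigma = 0.016  # s, gesture velocity bump width
    vel = np.zeros((len(TRACT_VARIABLES), n_kin))
    for t0, amp in zip(pulse_times, pulse_amps):
        k = rng.integers(2, 5)  # 2-4 articulators per gesture
        chans = rng.choice(len(TRACT_VARIABLES), size=k, replace=False)
        # sqrt(2/k) scaling keeps the summed squared-velocity pulse height
        # independent of how many articulators share the gesture
        bump = amp * np.sqrt(2.0 / k) * np.exp(-0.5 * ((t_kin - t0) / sigma) ** 2)
        signs = rng.choice([-1.0, 1.0], size=k)
        for c, s in zip(chans, signs):
            vel[c] += s * bump
    # small sensor noise on the velocities
    vel += 0.02 * rng.standard_normal(vel.shape)
    # leaky trapezoidal integration keeps positions bounded; the trapezoid
    # rule keeps the recovered (central-difference) velocity time-centred
    pos = np.zeros_like(vel)
    dt = 1.0 / cfg.fs_kin
    leak = 1.0 - 0.5 * dt
    for i in range(1, n_kin):
        pos[:, i] = pos[:, i - 1] * leak + 0.5 * (vel[:, i] + vel[:, i - 1]) * dt
    kin = TractKinematics(pos, cfg.fs_kin, list(TRACT_VARIABLES))
    info = {
        "pulse_times": np.asarray(pulse_times),
        "pulse_amplitudes": np.asarray(pulse_amps),
        "scheduled_cycles": np.asarray(sorted(scheduled), dtype=int),
        "skipped_cycles": np.asarray(skipped, dtype=int),
        "skipped_times": np.asarray(skipped_times),
        "realized_syllable_times": realized,
        "velocity": vel,
    }
    return kin, info


# --------------------------------------------------------------------------
# full session
# --------------------------------------------------------------------------

def _make_events(cfg: SessionConfig, rng) -> EventTable:
    rows = []
    t = 0.5
    utt_idx = 0
    period = 1.0 / cfg.syllable_rate
    while t + 1.3 * cfg.utterance_duration_s < cfg.duration_s - 0.5:
        # sentence lengths vary (+/-25% around the configured mean)
        dur = cfg.utterance_duration_s * rng.uniform(0.75, 1.25)
        dur = round(dur * cfg.syllable_rate) * period  # whole syllables
        onset, offset = t, t + dur
        is_error = rng.random() < cfg.error_trial_fraction
        # syllables tile the whole utterance so gesture pulses span it
        n_syl = int(round(dur * cfg.syllable_rate))
        rows.append(dict(onset_s=onset, offset_s=offset, label=f"utt{utt_idx:03d}",
                         tier="utterance", fluent=not is_error,
                         syllable_rate=n_syl / dur,
                         nucleus_s=np.nan, utterance=utt_idx, phone_class=""))
        for k in range(n_syl):
            nuc = onset + 0.5 * period + k * period
            lab = SYLLABLE_INVENTORY[rng.integers(len(SYLLABLE_INVENTORY))]
            rows.append(dict(onset_s=nuc - cfg.triplet_spacing_s, offset_s=nuc + cfg.triplet_spacing_s,
                             label=lab, tier="syllable", fluent=not is_error,
                             syllable_rate=np.nan, nucleus_s=nuc, utterance=utt_idx,
                             phone_class=""))
            for ph_t, ph_lab, ph_cls in (
                    (nuc - cfg.triplet_spacing_s, lab[0], "C"), (nuc, lab[-1], "V"),
                    (nuc + cfg.triplet_spacing_s, lab[0], "C")):
                rows.append(dict(onset_s=ph_t, offset_s=ph_t + 0.05, label=ph_lab,
                                 tier="phoneme", fluent=not is_error,
                                 syllable_rate=np.nan, nucleus_s=np.nan,
                                 utterance=utt_idx, phone_class=ph_cls))
        t = offset + cfg.gap_duration_s
        utt_idx += 1
    return EventTable(pd.DataFrame(rows))


def make_session(cfg: SessionConfig) -> SyntheticSession:
    """Compose a full synthetic session (LFP + kinematics + annotations).

    Channel phase offsets: channel 0 (most ventral, the reference) is fixed
    at zero; an ``antiphase_fraction`` subset sits at pi; all others near 0
    (Gaussian scatter ``phase_offset_jitter_sd``); an optional linear
    dorsoventral gradient is added on top.  Error utterances carry jittered
    movement-coupling phase and, in the LFP, a per-trial HG coupling-phase
    jitter of the same SD.
    """
    rng = np.random.default_rng(cfg.seed)
    n_lfp = int(round(cfg.duration_s * cfg.fs_lfp))
    seeds = rng.integers(0, 2**31 - 1, size=6)

    z = analytic_theta_carrier(cfg.fs_lfp, cfg.duration_s, cfg.theta_f0,
                               cfg.theta_bandwidth, int(seeds[0]))
    phase0 = np.unwrap(np.angle(z))

    # electrode geometry: a dorsoventral line, channel 0 most ventral (z=0)
    zpos = np.arange(cfg.n_channels) * cfg.electrode_spacing_mm
    coords = np.column_stack([np.zeros(cfg.n_channels), np.zeros(cfg.n_channels), zpos])

    if cfg.channel_phase_offsets is not None:
        offsets = np.asarray(cfg.channel_phase_offsets, dtype=float) % (2 * np.pi)
        antiphase = np.abs(((offsets - np.pi) + np.pi) % (2 * np.pi) - np.pi) < np.pi / 4
    else:
        offsets = rng.normal(0.0, cfg.phase_offset_jitter_sd, cfg.n_channels)
        n_anti = int(round(cfg.antiphase_fraction * max(cfg.n_channels - 1, 0)))
        antiphase = np.zeros(cfg.n_channels, dtype=bool)
        if n_anti > 0:
            anti_idx = rng.choice(np.arange(1, cfg.n_channels), size=n_anti, replace=False)
            antiphase[anti_idx] = True
            offsets[anti_idx] += np.pi
        offsets += cfg.phase_gradient_rad_per_mm * zpos
        offsets[0] = 0.0
        offsets = offsets % (2 * np.pi)

    events = _make_events(cfg, rng)
    utt = events.utterances
    # per-(channel, utterance) phase disorganization during error trials:
    # each site's local theta (and with it the HG coupling) rotates by an
    # independent random amount, degrading theta-movement coupling and the
    # across-site consistency of preferred phases
    error_jitter = rng.normal(0, cfg.error_phase_jitter_sd,
                              (cfg.n_channels, len(utt)))
    error_jitter[:, utt["fluent"].to_numpy(dtype=bool)] = 0.0

    kin, kin_info = gesture_pulse_kinematics(phase0, cfg, events, int(seeds[1]))

    # re-time syllable/phoneme annotations to the realized (cycle-snapped)
    # gesture times — what a forced alignment of the produced speech would
    # report — keeping annotations consistent with the kinematics
    real = kin_info.get("realized_syllable_times")
    if real is not None and len(real):
        df = events.df
        si = -1
        pk = 0
        for i in df.index:
            tier = df.at[i, "tier"]
            if tier == "syllable":
                si += 1
                pk = 0
                t_on, t0, t_coda = real[si]
                if np.isfinite(t0):
                    df.at[i, "nucleus_s"] = t0
                if np.isfinite(t_on):
                    df.at[i, "onset_s"] = t_on
                if np.isfinite(t_coda):
                    df.at[i, "offset_s"] = t_coda + 0.05
            elif tier == "phoneme" and si >= 0 and pk < 3:
                t = real[si][pk]
                if np.isfinite(t):
                    df.at[i, "onset_s"] = t
                    df.at[i, "offset_s"] = t + 0.05
                pk += 1

    # per-class, per-channel HG gain patterns (syllable code)
    code = rng.standard_normal((cfg.n_channels, len(SYLLABLE_INVENTORY)))
    syl = events.syllables
    class_of = {lab: i for i, lab in enumerate(SYLLABLE_INVENTORY)}

    data = np.empty((cfg.n_channels, n_lfp))
    hg_seeds = np.random.default_rng(int(seeds[2])).integers(0, 2**31 - 1, cfg.n_channels)
    bg_seeds = np.random.default_rng(int(seeds[3])).integers(0, 2**31 - 1, cfg.n_channels)
    t_lfp = np.arange(n_lfp) / cfg.fs_lfp
    from scipy.ndimage import gaussian_filter1d

    # inter-site locking weight: 1 during speech (starting coherence_lead_s
    # before each onset), 0 during silence, smoothed edges
    if cfg.coherence_modulated:
        w = np.zeros(n_lfp)
        for _, row in utt.iterrows():
            i0 = max(0, int((row.onset_s - cfg.coherence_lead_s) * cfg.fs_lfp))
            i1 = min(n_lfp, int(row.offset_s * cfg.fs_lfp))
            w[i0:i1] = 1.0
        w = gaussian_filter1d(w, 0.05 * cfg.fs_lfp)
    else:
        w = np.ones(n_lfp)
    ind_seeds = np.random.default_rng(int(seeds[4])).integers(0, 2**31 - 1,
                                                              cfg.n_channels)

    for c in range(cfg.n_channels):
        jit = np.zeros(n_lfp)
        for ui, row in utt.iterrows():
            if error_jitter[c, ui] != 0.0:
                i0, i1 = int(row.onset_s * cfg.fs_lfp), int(row.offset_s * cfg.fs_lfp)
                jit[i0:i1] = error_jitter[c, ui]
        if np.any(jit):
            jit = gaussian_filter1d(jit, 0.05 * cfg.fs_lfp)  # smooth edges
        z_c = z * np.exp(-1j * offsets[c])
        if cfg.coherence_modulated and c > 0:
            # channel keeps its own theta oscillator outside speech
            z_ind = analytic_theta_carrier(cfg.fs_lfp, cfg.duration_s, cfg.theta_f0,
                                           max(cfg.theta_bandwidth, 0.5),
                                           int(ind_seeds[c]))
            z_c = w * z_c + (1.0 - w) * z_ind
        z_c = z_c * np.exp(-1j * jit)
        phase_eff = np.angle(z_c)
        hg = pac_envelope_signal(phase_eff, cfg.pac_phase, cfg.pac_depth,
                                 cfg.hg_band, cfg.fs_lfp, int(hg_seeds[c]))
        if cfg.syllable_code_strength > 0:
            gain = np.ones(n_lfp)
            for _, srow in syl.iterrows():
                g = 1.0 + cfg.syllable_code_strength * np.tanh(
                    code[c, class_of[srow.label]])
                i0 = max(0, int((srow.nucleus_s - 0.12) * cfg.fs_lfp))
                i1 = min(n_lfp, int((srow.nucleus_s + 0.12) * cfg.fs_lfp))
                gain[i0:i1] = max(g, 0.1)
            hg = hg * gain
        bg = aperiodic_noise(cfg.fs_lfp, n_lfp, cfg.aperiodic_exponent, int(bg_seeds[c]))
        data[c] = (cfg.theta_amplitude * np.real(z_c)
                   + cfg.background_amplitude * bg
                   + cfg.hg_amplitude * hg)

    rec = Recording(
        data=data, fs=cfg.fs_lfp,
        ch_names=[f"ch{c:02d}" for c in range(cfg.n_channels)],
        coords_mm=coords, regions=["vSMC"] * cfg.n_channels,
        responsive=np.ones(cfg.n_channels, dtype=bool),
    )
    ground_truth = {
        "phase_offsets": offsets,
        "antiphase": antiphase,
        "pac_phase": cfg.pac_phase,
        "pac_depth": cfg.pac_depth,
        "ac_preferred_phase": cfg.ac_preferred_phase,
        "error_trial": (~utt["fluent"].to_numpy(dtype=bool)),
        "error_jitter": error_jitter,
        "pulse_times": kin_info["pulse_times"],
        "skipped_cycles": kin_info["skipped_cycles"],
        "skipped_times": kin_info["skipped_times"],
        "scheduled_cycles": kin_info["scheduled_cycles"],
        "syllable_code": code,
        "theta_phase_ref": phase0,
    }
    return SyntheticSession(recording=rec, kinematics=kin, events=events,
                            ground_truth=ground_truth, config=cfg)
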