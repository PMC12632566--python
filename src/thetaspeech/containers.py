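"""Core data containers shared across the analysis modules.

The containers are deliberately thin: numpy arrays plus the metadata the
analyses need (sampling rates, channel geometry, event annotations).  Event
annotations live in a pandas DataFrame with one row per event and a ``tier``
column distinguishing utterances, syllables and phonemes — the same layout
the on-disk TSV uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventTable",
    "TractKinematics",
    "Spectrum",
    "SpectralFit",
    "BandSignal",
    "Coherogram",
    "CouplingResult",
    "TRFModel",
    "PhaseAlignedEpochs",
    "DecodingResult",
    "PeriodicityResult",
]


EVENT_COLUMNS = ["onset_s", "offset_s", "label", "tier"]


@dataclass
class Recording:
    """Multichannel field-potential recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage traces.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
    coords_mm : ndarray, shape (n_channels, 3)
        Electrode coordinates in mm (x, y, z); z is the dorsoventral axis.
    regions : list of str
        Anatomical label per channel (e.g. ``"vSMC"``).
    responsive : ndarray of bool
        Speech-responsiveness flag per channel.
    """

    data: np.ndarray
    fs: float
    ch_names: list
    coords_mm: np.ndarray
    regions: list
    responsive: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[0]
        self.coords_mm = np.asarray(self.coords_mm, dtype=float).reshape(n, 3)
        self.responsive = np.asarray(self.responsive, dtype=bool).reshape(n)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


class EventTable:
    """Time-aligned annotations: utterances, syllables, phonemes.

    Wraps a DataFrame with at least ``onset_s, offset_s, label, tier``.
    Utterance rows may carry ``fluent`` (bool) and ``syllable_rate`` (syl/s);
    syllable rows carry ``nucleus_s`` (time of the vowel nucleus) and
    ``utterance`` (index of the parent utterance row).
    """

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df).reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def tier(self, name: str) -> pd.DataFrame:
        return self.df[self.df["tier"] == name].reset_index(drop=True)

    @property
    def utterances(self) -> pd.DataFrame:
        return self.tier("utterance")

    @property
    def syllables(self) -> pd.DataFrame:
        return self.tier("syllable")

    @property
    def phonemes(self) -> pd.DataFrame:
        return self.tier("phoneme")

    def speech_mask(self, fs: float, n_samples: int, pad_s: float = 0.0) -> np.ndarray:
        """Boolean per-sample mask covering utterance spans (padded by pad_s)."""
        mask = np.zeros(n_samples, dtype=bool)
        for _, row in self.utterances.iterrows():
            i0 = max(0, int(round((row.onset_s - pad_s) * fs)))
            i1 = min(n_samples, int(round((row.offset_s + pad_s) * fs)))
            mask[i0:i1] = True
        return mask

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)


@dataclass
class TractKinematics:
    """Vocal-tract trajectories (tract variables x samples) at kinematic rate.

    ``ac`` holds the derived Articulatory Change series (sum of squared
    velocities across tract variables) once computed.
    """

    data: np.ndarray
    fs: float
    names: list
    ac: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("names must match number of tract variables")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    window_s: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class SpectralFit:
    """Aperiodic (1/f) + Gaussian-peaks decomposition of a power spectrum."""

    aperiodic_offset: float
    aperiodic_exponent: float
    peaks: list  # of (center_hz, height_log10, width_hz)
    fit_range: tuple
    goodness: float  # R^2 of the full model in log10-power space

    @property
    def peak_centers(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


@dataclass
class BandSignal:
    """Band-limited analytic signal.

    Phase convention: 0 at the waveform positive peak, +/-pi at the trough.
    """

    band: tuple
    amplitude: np.ndarray
    phase: np.ndarray
    fs: float

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


@dataclass
class Coherogram:
    times: np.ndarray  # s relative to event
    freqs: np.ndarray
    coherence: np.ndarray  # (n_freqs, n_times), PLV in [0, 1]
    n_pairs: int
    baseline_window: tuple = (-1.0, 0.0)


@dataclass
class CouplingResult:
    """Tort modulation-index coupling between a phase and a magnitude series."""

    mi: float
    profile: np.ndarray  # mean magnitude per phase bin, normalized to sum 1
    preferred_phase: float  # radians in [0, 2pi)
    p_value: float | None = None
    n_surrogates: int = 0
    surrogate_mi: np.ndarray | None = None
    bin_width_deg: float = 15.0

    @property
    def bin_centers(self) -> np.ndarray:
        n = len(self.profile)
        return (np.arange(n) + 0.5) * 2 * np.pi / n


@dataclass
class TRFModel:
    """Lagged linear (temporal response function) encoding model."""

    lags_s: np.ndarray
    weights: np.ndarray  # (n_features, n_lags)
    ridge_lambda: float
    cv_r2: float
    feature_names: list
    intercept: float = 0.0
    unique_r2: dict = field(default_factory=dict)


@dataclass
class PhaseAlignedEpochs:
    """Per-trial signals resampled onto a uniform theta-phase axis.

    ``phase_axis`` spans [-9pi, 7pi]; phase 0 is the anchor trough.  Signals
    are stored as dict name -> array (n_trials, n_points) (or
    (n_trials, n_channels, n_points) for multichannel sets).  ``valid`` marks
    phase points actually covered by the trial (no extrapolation).
    """

    phase_axis: np.ndarray
    signals: dict
    anchor_trough_time_s: np.ndarray
    labels: pd.DataFrame
    valid: np.ndarray  # (n_trials, n_points) bool

    @property
    def n_trials(self) -> int:
        return len(self.anchor_trough_time_s)


@dataclass
class DecodingResult:
    bin_centers: np.ndarray  # radians on the warped phase axis
    accuracy: np.ndarray  # proportion per bin
    null_mean: np.ndarray
    null_ci: np.ndarray  # (n_bins, 2) 95% CI under label shuffling
    p_values: np.ndarray
    significant_bins: np.ndarray  # bool mask after FDR
    scores: np.ndarray  # (n_bins, n_trials, n_classes) decision scores
    labels: np.ndarray  # true class index per trial
    classes: np.ndarray
    n_classes: int

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


@dataclass
class PeriodicityResult:
    lags_s: np.ndarray
    acf: np.ndarray
    secondary_peak: float
    secondary_peak_lag_s: float
    band_power: float
    found: bool = True
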