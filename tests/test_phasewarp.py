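"""Trough anchoring, phase warping, phase-locked averages, decoding."""

import numpy as np
import pandas as pd
import pytest

from thetaspeech import phasewarp
from thetaspeech.containers import BandSignal, PhaseAlignedEpochs


def _cosine_band(fs=1000.0, dur=10.0, f0=8.2):
    t = np.arange(int(dur * fs)) / fs
    phase = (2 * np.pi * f0 * t + np.pi) % (2 * np.pi) - np.pi
    return BandSignal(band=(6, 10), amplitude=np.ones(t.size), phase=phase,
                      fs=fs), t


class TestAnchorTrough:
    def test_within_half_cycle_and_phase_pi(self):
        bs, t = _cosine_band()
        fs, f0 = bs.fs, 8.2
        idx = phasewarp.locate_anchor_trough(bs, 5.0)
        assert abs(idx / fs - 5.0) <= 0.5 / f0 + 2 / fs
        assert abs(abs(bs.phase[idx]) - np.pi) < 2 * np.pi * f0 / fs

    def test_tie_breaks_earlier(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        f0 = 5.0  # troughs at 0.1, 0.3, 0.5, ... for cos(2 pi 5 t)
        phase = (2 * np.pi * f0 * t + np.pi) % (2 * np.pi) - np.pi
        bs = BandSignal(band=(4, 6), amplitude=np.ones(t.size), phase=phase,
                        fs=fs)
        idx = phasewarp.locate_anchor_trough(bs, 2.0)  # midway 1.9 and 2.1
        assert idx / fs == pytest.approx(1.9, abs=2 / fs)

    def test_anchor_outside_signal_errors(self):
        bs, _ = _cosine_band(dur=2.0)
        with pytest.raises(ValueError):
            phasewarp.locate_anchor_trough(bs, 5.0)


class TestPhaseWarp:
    def test_axis_endpoints_exact(self):
        bs, t = _cosine_band(dur=4.0)
        anchor = phasewarp.locate_anchor_trough(bs, 2.0)
        ep = phasewarp.phase_warp_epochs([bs.phase], {"x": [np.cos(bs.phase)]},
                                         [anchor], bs.fs)
        assert ep.phase_axis[0] == -9 * np.pi
        assert ep.phase_axis[-1] == 7 * np.pi

    def test_constant_frequency_equals_time_resampling(self):
        fs, f0 = 1000.0, 8.0
        t = np.arange(int(6 * fs)) / fs
        phase = 2 * np.pi * f0 * t
        sig = np.sin(2 * np.pi * 1.3 * t)  # arbitrary smooth signal
        anchor = int(3.0 * fs)
        n_points = 320
        ep = phasewarp.phase_warp_epochs(
            [phase], {"x": [sig]}, [anchor], fs, n_points=n_points)
        # constant frequency: phase axis is a linear time axis
        times = anchor / fs + ep.phase_axis / (2 * np.pi * f0)
        expect = np.interp(times, t, sig)
        valid = ep.valid[0]
        assert np.max(np.abs(ep.signals["x"][0][valid] - expect[valid])) < 1e-6

    def test_warped_phase_is_trough_at_zero(self):
        bs, t = _cosine_band(dur=4.0)
        anchor = phasewarp.locate_anchor_trough(bs, 2.0)
        ep = phasewarp.phase_warp_epochs([bs.phase], {"ph": [bs.phase]},
                                         [anchor], bs.fs, n_points=1601)
        i0 = np.argmin(np.abs(ep.phase_axis))
        wrapped = (ep.signals["ph"][0][i0] + np.pi) % (2 * np.pi) - np.pi
        assert abs(abs(wrapped) - np.pi) < 0.05

    def test_phase_slip_errors(self):
        fs = 1000.0
        u = np.linspace(0, 40 * np.pi, int(4 * fs))
        u[2000:2200] = u[2000] - 0.5  # 200 ms decreasing stretch
        with pytest.raises(RuntimeError):
            phasewarp.phase_warp_epochs([u], {"x": [np.zeros(u.size)]},
                                        [1000], fs)


def _synthetic_epochs(rng, n_trials=40, n_points=160, locked_at=None,
                      labels=None):
    axis = np.linspace(-9 * np.pi, 7 * np.pi, n_points)
    arr = 0.2 * np.abs(rng.standard_normal((n_trials, n_points))) + 0.1
    if locked_at is not None:
        for k in (-1, 0, 1):
            center = locked_at + 2 * np.pi * k
            arr += 1.0 * np.exp(-0.5 * ((axis - center) / 0.4) ** 2)
    lab = pd.DataFrame({"label": labels if labels is not None
                        else ["a"] * n_trials})
    return PhaseAlignedEpochs(phase_axis=axis, signals={"ac": arr},
                              anchor_trough_time_s=np.zeros(n_trials),
                              labels=lab,
                              valid=np.ones((n_trials, n_points), bool))


class TestPhaseLockedAverage:
    def test_locked_signal_exceeds_null_at_injected_phase(self, rng):
        ep = _synthetic_epochs(rng, locked_at=2.0)
        out = phasewarp.phase_locked_average(ep, "ac", n_surrogates=50, seed=0)
        for k in (-1, 0, 1):
            i = np.argmin(np.abs(ep.phase_axis - (2.0 + 2 * np.pi * k)))
            assert out["mean"][i] > out["null_band"][1][i]

    def test_unlocked_signal_within_band(self, rng):
        ep = _synthetic_epochs(rng, locked_at=None)
        out = phasewarp.phase_locked_average(ep, "ac", n_surrogates=50, seed=0)
        inside = (out["mean"] >= out["null_band"][0]) & \
                 (out["mean"] <= out["null_band"][1])
        assert inside.mean() > 0.9

    def test_peak_histogram_normalized(self, rng):
        ep = _synthetic_epochs(rng, locked_at=1.0)
        out = phasewarp.phase_locked_average(ep, "ac", n_surrogates=50, seed=1)
        assert out["peak_hist"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_few_trials_errors(self, rng):
        ep = _synthetic_epochs(rng, n_trials=5)
        with pytest.raises(ValueError):
            phasewarp.phase_locked_average(ep, "ac")


def _coded_epochs(rng, n_classes=4, reps=14, n_ch=8, n_points=160,
                  code_phase=0.5, noise=0.3):
    axis = np.linspace(-9 * np.pi, 7 * np.pi, n_points)
    labels = np.repeat([f"s{k}" for k in range(n_classes)], reps)
    rng.shuffle(labels)
    code = rng.standard_normal((n_classes, n_ch))
    bump = np.exp(-0.5 * ((axis - code_phase) / 0.3) ** 2)
    n_trials = labels.size
    arr = noise * rng.standard_normal((n_trials, n_ch, n_points))
    for t, lab in enumerate(labels):
        k = int(lab[1:])
        arr[t] += code[k][:, None] * bump[None, :]
    lab = pd.DataFrame({"label": labels})
    return PhaseAlignedEpochs(phase_axis=axis, signals={"hg": arr},
                              anchor_trough_time_s=np.zeros(n_trials),
                              labels=lab,
                              valid=np.ones((n_trials, n_points), bool))


class TestDecoder:
    def test_peak_accuracy_at_injected_phase(self, rng):
        ep = _coded_epochs(rng, code_phase=0.5)
        res = phasewarp.sliding_phase_decoder(
            ep, window_rad=0.3, step_rad=0.3, n_shuffles=20,
            min_repetitions=5, phase_range=(-np.pi, np.pi), seed=0)
        peak = res.bin_centers[np.argmax(res.accuracy)]
        assert abs(peak - 0.5) <= 0.3

    def test_separable_classes_perfect_in_informative_bin(self, rng):
        ep = _coded_epochs(rng, n_classes=2, reps=12, noise=0.001)
        res = phasewarp.sliding_phase_decoder(
            ep, window_rad=0.3, step_rad=0.3, n_shuffles=10,
            min_repetitions=5, phase_range=(0.0, 1.0), seed=0)
        assert res.accuracy.max() == pytest.approx(1.0)

    def test_shuffle_null_at_chance(self, rng):
        ep = _coded_epochs(rng, n_classes=4, reps=12)
        res = phasewarp.sliding_phase_decoder(
            ep, window_rad=0.3, step_rad=0.5, n_shuffles=60,
            min_repetitions=5, phase_range=(0.0, 1.5), seed=1)
        for b in range(res.bin_centers.size):
            lo, hi = res.null_ci[b]
            assert lo <= 1 / res.n_classes + 0.05
            assert abs(res.null_mean[b] - 0.25) < 0.06

    def test_small_classes_dropped(self, rng):
        ep = _coded_epochs(rng, n_classes=3, reps=12)
        ep.labels.loc[:2, "label"] = "rare"
        with pytest.warns(UserWarning, match="dropped"):
            phasewarp.sliding_phase_decoder(
                ep, window_rad=0.3, step_rad=1.0, n_shuffles=5,
                min_repetitions=5, phase_range=(0.0, 1.0), seed=0)


class TestCombineBins:
    def _result(self, rng, sig_mask, accs):
        n_bins = len(accs)
        n_trials, K = 40, 4
        labels = np.repeat(np.arange(K), 10)
        scores = rng.standard_normal((n_bins, n_trials, K)) * 0.01
        for b in range(n_bins):
            # make per-bin scores produce exactly acc[b] accuracy
            n_right = int(round(accs[b] * n_trials))
            for t in range(n_trials):
                good = t < n_right
                scores[b, t, labels[t]] += 10.0 if good else -10.0
                scores[b, t, (labels[t] + 1) % K] += 0.0 if good else 20.0
        from thetaspeech.containers import DecodingResult
        return DecodingResult(
            bin_centers=np.arange(n_bins, dtype=float),
            accuracy=np.asarray(accs), null_mean=np.full(n_bins, 0.25),
            null_ci=np.tile([0.2, 0.3], (n_bins, 1)),
            p_values=np.where(sig_mask, 0.01, 0.5),
            significant_bins=np.asarray(sig_mask), scores=scores,
            labels=labels, classes=np.arange(K), n_classes=K)

    def test_single_significant_bin_equals_its_accuracy(self, rng):
        res = self._result(rng, [False, True, False], [0.3, 0.7, 0.4])
        out = phasewarp.combine_significant_bins(res)
        assert out["combined_accuracy"] == pytest.approx(0.7, abs=0.025)

    def test_no_significant_bins_status(self, rng):
        res = self._result(rng, [False, False], [0.3, 0.3])
        out = phasewarp.combine_significant_bins(res)
        assert out["status"] == "no-significant-bins"
        assert out["combined_accuracy"] is None

    def test_confusion_rows_sum_to_class_counts(self, rng):
        res = self._result(rng, [True, True], [0.5, 0.9])
        out = phasewarp.combine_significant_bins(res)
        np.testing.assert_array_equal(out["confusion"].sum(axis=1),
                                      np.full(4, 10))
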