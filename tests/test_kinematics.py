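"""Articulatory change, pulse analysis, mTRF encoding models."""

import numpy as np
import pandas as pd
import pytest

from thetaspeech import kinematics
from thetaspeech.containers import EventTable, TractKinematics


def _kin(data, fs=100.0):
    data = np.atleast_2d(data)
    return TractKinematics(data, fs, [f"v{i}" for i in range(data.shape[0])])


def _utts(spans):
    return EventTable(pd.DataFrame({
        "onset_s": [s[0] for s in spans], "offset_s": [s[1] for s in spans],
        "label": "u", "tier": "utterance"}))


class TestArticulatoryChange:
    def test_constant_trajectories_zero(self):
        ac = kinematics.articulatory_change(_kin(np.full((3, 500), 2.5)))
        np.testing.assert_allclose(ac, 0.0, atol=1e-20)

    def test_linear_ramp_closed_form(self):
        fs, v = 100.0, 3.0
        x = v * np.arange(1000) / fs
        ac = kinematics.articulatory_change(_kin(x), smooth_ms=0, lowpass_hz=None)
        np.testing.assert_allclose(ac[1:-1], v**2, rtol=1e-9)

    def test_six_variable_sum_oracle(self, rng):
        data = rng.standard_normal((6, 800))
        total = kinematics.articulatory_change(_kin(data), smooth_ms=0,
                                               lowpass_hz=None)
        per = sum(kinematics.articulatory_change(_kin(data[i]), smooth_ms=0,
                                                 lowpass_hz=None)
                  for i in range(6))
        np.testing.assert_allclose(total, per, atol=1e-12)

    def test_offset_invariance_and_quadratic_scaling(self, rng):
        data = rng.standard_normal((2, 600))
        base = kinematics.articulatory_change(_kin(data), smooth_ms=0,
                                              lowpass_hz=None)
        shifted = kinematics.articulatory_change(_kin(data + 5.0), smooth_ms=0,
                                                 lowpass_hz=None)
        scaled = kinematics.articulatory_change(_kin(3.0 * data), smooth_ms=0,
                                                lowpass_hz=None)
        np.testing.assert_allclose(shifted, base, atol=1e-12)
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-9)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            kinematics.articulatory_change(_kin(np.zeros((2, 2))))


class TestPulseAnalysis:
    def test_strict_8hz_train(self):
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        ac = np.zeros(t.size)
        for t0 in np.arange(0.5, 9.5, 0.125):
            ac += np.exp(-0.5 * ((t - t0) / 0.01) ** 2)
        res = kinematics.ac_pulse_analysis(ac, fs, _utts([(0.5, 9.5)]))
        assert res["median_rate"] == pytest.approx(8.0, abs=0.15)
        np.testing.assert_allclose(res["ipis"], 0.125, atol=0.011)

    def test_threshold_above_max_no_pulses(self):
        fs = 100.0
        ac = np.abs(np.sin(np.arange(1000) / 10.0))
        res = kinematics.ac_pulse_analysis(ac, fs, _utts([(0, 10)]),
                                           threshold=10.0)
        assert res["pulse_times"].size == 0

    def test_all_zero_ac(self):
        res = kinematics.ac_pulse_analysis(np.zeros(1000), 100.0,
                                           _utts([(0, 10)]))
        assert res["pulse_times"].size == 0


class TestMtrf:
    def test_kernel_recovery_noiseless(self, rng):
        fs = 100.0
        n = 6000
        feat = np.zeros(n)
        feat[rng.choice(np.arange(100, n - 100), 150, replace=False)] = 1.0
        lags = np.arange(-20, 21)
        kernel = np.exp(-0.5 * ((lags - 5) / 4.0) ** 2)
        target = np.zeros(n)
        for l, k in zip(lags, kernel):
            target += np.roll(feat, l) * k
        model = kinematics.fit_mtrf(feat, target, fs, lags=(-0.2, 0.2),
                                    lambdas=[1e-6])
        err = np.max(np.abs(model.weights[0] - kernel))
        assert err < 0.01 * kernel.max()

    def test_huge_ridge_shrinks_weights(self, rng):
        fs = 100.0
        feat = rng.standard_normal(2000)
        target = np.roll(feat, 3) + 0.1 * rng.standard_normal(2000)
        model = kinematics.fit_mtrf(feat, target, fs, lags=(-0.1, 0.1),
                                    lambdas=[1e12])
        assert np.max(np.abs(model.weights)) < 1e-3

    def test_permuted_target_no_skill(self, rng):
        fs = 100.0
        feat = rng.standard_normal(3000)
        target = np.roll(feat, 5)
        r2 = []
        for _ in range(10):
            m = kinematics.fit_mtrf(feat, rng.permutation(target), fs,
                                    lags=(-0.1, 0.1), lambdas=[1.0, 100.0])
            r2.append(m.cv_r2)
        assert np.mean(r2) <= 0.01

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            kinematics.fit_mtrf(np.zeros(100), np.zeros(99), 100.0)
        with pytest.raises(ValueError):
            kinematics.fit_mtrf(np.zeros(100), np.zeros(100), 100.0, cv_folds=1)


class TestUniqueVariance:
    def _design(self, rng, n=4000):
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        return f1, f2

    def test_duplicated_feature_zero(self, rng):
        f1, _ = self._design(rng)
        target = np.roll(f1, 2) + 0.1 * rng.standard_normal(f1.size)
        dv = kinematics.unique_variance(np.vstack([f1, f1]), target, 100.0, 0,
                                        lags=(-0.05, 0.05), lambdas=[1.0])
        assert abs(dv) < 0.02

    def test_sole_informative_feature(self, rng):
        f1, f2 = self._design(rng)
        target = np.roll(f1, 2) + 0.05 * rng.standard_normal(f1.size)
        full = kinematics.fit_mtrf(np.vstack([f1, f2]), target, 100.0,
                                   lags=(-0.05, 0.05), lambdas=[1.0])
        dv = kinematics.unique_variance(np.vstack([f1, f2]), target, 100.0, 0,
                                        lags=(-0.05, 0.05), lambdas=[1.0])
        assert dv == pytest.approx(full.cv_r2, abs=0.05)

    def test_grows_with_effect_size(self, rng):
        f1, f2 = self._design(rng)
        noise = rng.standard_normal(f1.size)
        dvs = []
        for g in (0.2, 0.6, 1.2):
            target = g * np.roll(f1, 2) + np.roll(f2, 1) + 0.5 * noise
            dvs.append(kinematics.unique_variance(
                np.vstack([f1, f2]), target, 100.0, 0,
                lags=(-0.05, 0.05), lambdas=[1.0]))
        assert dvs[0] < dvs[1] < dvs[2]

    def test_single_feature_design_errors(self, rng):
        f1, _ = self._design(rng, 500)
        with pytest.raises(ValueError):
            kinematics.unique_variance(f1, np.roll(f1, 1), 100.0, 0)


class TestResponseProfile:
    def test_flat_model_no_peaks(self):
        from thetaspeech.containers import TRFModel
        m = TRFModel(lags_s=np.linspace(-0.1, 0.1, 21),
                     weights=np.zeros((1, 21)), ridge_lambda=1.0,
                     cv_r2=0.0, feature_names=["f0"])
        lags, curve, peaks = kinematics.trf_response_profile(m, "f0")
        assert peaks.size == 0

    def test_triplet_kernel_spacing(self, rng):
        # a vowel-like kernel: three pulses 0.125 s apart
        fs = 100.0
        n = 8000
        feat = np.zeros(n)
        feat[np.arange(200, n - 200, 60)] = 1.0
        lag_grid = np.arange(-40, 41)
        kernel = sum(a * np.exp(-0.5 * ((lag_grid - d) / 2.0) ** 2)
                     for a, d in ((0.7, -12.5), (1.0, 0.0), (0.7, 12.5)))
        target = np.zeros(n)
        for l, k in zip(lag_grid, kernel):
            target += np.roll(feat, l) * k
        target += 0.02 * rng.standard_normal(n)
        model = kinematics.fit_mtrf(feat, target, fs, lags=(-0.4, 0.4),
                                    lambdas=[1e-3], feature_names=["vowel"])
        lags, curve, peaks = kinematics.trf_response_profile(model, "vowel")
        central = peaks[np.abs(peaks) < 0.2]
        assert central.size == 3
        assert np.mean(np.diff(central)) == pytest.approx(0.125, abs=0.01)

    def test_unknown_feature_errors(self):
        from thetaspeech.containers import TRFModel
        m = TRFModel(lags_s=np.zeros(3), weights=np.zeros((1, 3)),
                     ridge_lambda=1.0, cv_r2=0.0, feature_names=["a"])
        with pytest.raises(ValueError):
            kinematics.trf_response_profile(m, "b")
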