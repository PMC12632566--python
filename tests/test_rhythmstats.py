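"""Rhythm periodicity, rate relations, matched resampling, fluency
contrasts, and the shared circular tests."""

import numpy as np
import pandas as pd
import pytest

from thetaspeech import circstats, rhythmstats, synthgen


class TestAcfPeriodicity:
    def test_pure_sinusoid_peak_one_at_period(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        res = rhythmstats.acf_periodicity(np.cos(2 * np.pi * 8.2 * t), fs,
                                          band=(6, 10))
        assert res.secondary_peak == pytest.approx(1.0, abs=0.01)
        assert res.secondary_peak_lag_s == pytest.approx(1 / 8.2, abs=0.005)

    def test_amplitude_invariance(self):
        fs = 500.0
        x = synthgen.theta_carrier(fs, 30.0, 8.2, 1.5, seed=0)
        a = rhythmstats.acf_periodicity(x, fs).secondary_peak
        b = rhythmstats.acf_periodicity(123.0 * x, fs).secondary_peak
        assert a == pytest.approx(b, abs=1e-9)

    def test_white_noise_below_oscillator_floor(self, rng):
        # band-filtered white noise: secondary peak stays below narrowband
        # oscillators and below the matched filter-only null 95th percentile
        fs = 500.0
        null = [rhythmstats.acf_periodicity(
            np.random.default_rng(s).standard_normal(int(30 * fs)), fs)
            .secondary_peak for s in range(20)]
        x = synthgen.theta_carrier(fs, 30.0, 8.2, 1.0, seed=1)
        osc = rhythmstats.acf_periodicity(x, fs).secondary_peak
        assert osc > np.percentile(null, 95)

    def test_monotone_in_generator_bandwidth(self):
        fs = 500.0
        peaks = []
        for bw in (0.5, 1.5, 3.0):
            vals = [rhythmstats.acf_periodicity(
                synthgen.theta_carrier(fs, 30.0, 8.2, bw, seed=s), fs)
                .secondary_peak for s in range(3)]
            peaks.append(np.mean(vals))
        assert peaks[0] > peaks[1] > peaks[2]

    def test_short_signal_errors(self):
        with pytest.raises(ValueError):
            rhythmstats.acf_periodicity(np.zeros(400), 500.0, band=(6, 10))


class TestRatePeriodicity:
    def test_even_split_sizes(self, rng):
        rates = rng.uniform(2, 6, 12)
        per = rng.uniform(0, 1, 12)
        out = rhythmstats.rate_periodicity_analysis(per, rates, n_perm=100)
        assert len(out["fast_idx"]) == len(out["slow_idx"]) == 6

    def test_monotone_relation_rho_one(self):
        rates = np.linspace(2, 6, 10)
        per = np.linspace(0.2, 0.9, 10)
        out = rhythmstats.rate_periodicity_analysis(per, rates, n_perm=500,
                                                    seed=0)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["spearman_p_perm"] < 0.01
        assert out["fast_median"] > out["slow_median"]

    def test_null_calibration(self, rng):
        # independent periodicity and rates: ~alpha rejections
        rej = 0
        reps = 100
        for _ in range(reps):
            out = rhythmstats.rate_periodicity_analysis(
                rng.uniform(0, 1, 12), rng.uniform(2, 6, 12), n_perm=99,
                seed=int(rng.integers(2**31)))
            rej += out["spearman_p_perm"] < 0.05
        assert rej / reps < 0.12

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            rhythmstats.rate_periodicity_analysis([1, 2, 3], [1, 2, 3])


def _trials(n, rate=4.0, dur=2.0, rng=None):
    rate = rate + (rng.normal(0, 0.3, n) if rng is not None else 0)
    onset = np.arange(n) * 3.0
    return pd.DataFrame({"onset_s": onset, "offset_s": onset + dur,
                         "syllable_rate": rate})


class TestMatchedResample:
    def test_identical_covariates_match_exactly(self, rng):
        err = _trials(12, rng=rng)
        pool = pd.concat([err, _trials(30, rate=5.5, rng=rng)],
                         ignore_index=True)
        out = rhythmstats.matched_trial_resample(err, pool, n_resamples=20,
                                                 seed=0)
        assert not out["excluded"]
        np.testing.assert_allclose(out["matched_covariate_medians"],
                                   out["error_covariate_medians"], rtol=0.05)

    def test_resample_metadata_and_uniqueness(self, rng):
        err = _trials(10, rng=rng)
        pool = _trials(40, rate=4.3, rng=rng)
        out = rhythmstats.matched_trial_resample(err, pool, n_resamples=200,
                                                 seed=1)
        assert out["n_resamples"] == 200
        for rs in out["resamples"][:20]:
            assert len(rs) == 10
            assert len(np.unique(rs)) == 10  # no reuse within one resample

    def test_few_error_trials_excluded(self, rng):
        out = rhythmstats.matched_trial_resample(_trials(9, rng=rng),
                                                 _trials(40, rng=rng))
        assert out["excluded"]

    def test_small_pool_errors(self, rng):
        with pytest.raises(ValueError):
            rhythmstats.matched_trial_resample(_trials(12, rng=rng),
                                               _trials(5, rng=rng))


class TestFluencyContrast:
    def _electrode_trials(self, rng, n_trials, jitter_sd=0.0, offset=0.0):
        phases, acs = [], []
        for t in range(n_trials):
            fs = 250.0
            tt = np.arange(int(4 * fs)) / fs
            ph = (2 * np.pi * 8.2 * tt + rng.uniform(0, 2 * np.pi))
            eps = rng.normal(0, jitter_sd) if jitter_sd else 0.0
            mag = 1.0 + 0.6 * np.cos(ph - (np.deg2rad(301) + offset + eps))
            phases.append(ph % (2 * np.pi))
            acs.append(mag)
        return phases, acs

    def test_identical_groups_no_difference(self, rng):
        per_el = []
        for e in range(6):
            ph, ac = self._electrode_trials(rng, 20, offset=0.1 * e)
            per_el.append((ph, ac))
        fluent = np.zeros(20, bool)
        fluent[::2] = True  # alternating: both "groups" identical in law
        out = rhythmstats.fluency_coupling_contrast(per_el, fluent, seed=0)
        assert abs(out["mi_difference"]) < 0.005
        assert out["consistency_fluent"] > 0.99
        assert out["consistency_error"] > 0.99

    def test_jittered_error_trials_detected(self, rng):
        per_el = []
        fluent = np.zeros(30, bool)
        fluent[:20] = True
        for e in range(8):
            phf, acf_ = self._electrode_trials(rng, 20, offset=0.1 * e)
            phe, ace = self._electrode_trials(rng, 10, jitter_sd=1.0,
                                              offset=0.1 * e)
            per_el.append((phf + phe, acf_ + ace))
        out = rhythmstats.fluency_coupling_contrast(per_el, fluent, seed=0)
        assert out["mi_difference"] > 0
        assert out["mi_p"] < 0.05
        assert out["consistency_error"] < out["consistency_fluent"]


class TestCircTests:
    def test_identical_angles_mrl_one(self):
        out = rhythmstats.circ_tests(np.full(20, 1.3))
        assert out["mrl"] == pytest.approx(1.0)

    def test_uniform_calibration(self, rng):
        rej = 0
        reps = 200
        for _ in range(reps):
            out = rhythmstats.circ_tests(rng.uniform(0, 2 * np.pi, 100))
            rej += out["rayleigh_p"] < 0.05
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_von_mises_power(self, rng):
        for _ in range(20):
            angles = rng.vonmises(0.7, 2.0, 50)
            out = rhythmstats.circ_tests(angles)
            assert out["rayleigh_p"] < 0.05

    def test_rayleigh_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        angles = rng.vonmises(0.0, 1.0, 40)
        out = rhythmstats.circ_tests(angles)
        z_pg, p_pg = pg.circ_rayleigh(angles)
        assert out["rayleigh_p"] == pytest.approx(p_pg, rel=1e-3)

    def test_watson_two_sample_separates_shifted(self, rng):
        a = rng.vonmises(0.0, 3.0, 40)
        b = rng.vonmises(np.pi, 3.0, 40)
        out = rhythmstats.circ_tests(a, b, n_perm=200, seed=0)
        assert out["watson_p"] < 0.05

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            rhythmstats.circ_tests([0.1, 0.2, 0.3])


class TestFisherDispersion:
    def test_different_concentration_detected(self, rng):
        tight = rng.vonmises(0.0, 20.0, 40)
        loose = rng.vonmises(0.0, 1.0, 40)
        stat, p = circstats.fisher_dispersion_test(tight, loose, seed=0)
        assert p < 0.01

    def test_equal_concentration_calibrated(self, rng):
        rej = 0
        reps = 100
        for _ in range(reps):
            a = rng.vonmises(0.0, 3.0, 30)
            b = rng.vonmises(1.0, 3.0, 30)  # same kappa, different mean
            _, p = circstats.fisher_dispersion_test(a, b, n_perm=200,
                                                    seed=int(rng.integers(2**31)))
            rej += p < 0.05
        assert rej / reps < 0.12
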