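"""RMS windowing, mu-law/Z-score normalization, resampling, trial splits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgkin import signal_prep as sp


class TestRmsWindows:
    def test_constant_signal_rms_is_magnitude(self):
        emg = np.full((500, 3), -2.5)
        rms = sp.compute_rms_windows(emg, fs=1000, window_ms=100, step_ms=50)
        assert np.allclose(rms, 2.5)

    def test_two_sample_window_value(self):
        # sqrt((9 + 16) / 2) = sqrt(12.5)
        rms = sp.compute_rms_windows(np.array([3.0, 4.0])[:, None], fs=1000,
                                     window_ms=2, step_ms=1)
        assert rms.shape == (1, 1)
        assert np.isclose(rms[0, 0], np.sqrt(12.5))

    def test_window_count_formula(self):
        # floor((2000 - 200)/100) + 1 = 19
        rms = sp.compute_rms_windows(np.zeros((2000, 2)), fs=2000,
                                     window_ms=100, step_ms=50)
        assert rms.shape == (19, 2)

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        # integer number of periods inside each window
        fs, f0, amp = 2000, 100, 3.0
        t = np.arange(4000) / fs
        emg = amp * np.sin(2 * np.pi * f0 * t)[:, None]
        rms = sp.compute_rms_windows(emg, fs, window_ms=100, step_ms=100)
        assert np.allclose(rms, amp / np.sqrt(2), atol=1e-6)

    def test_short_signal_error_names_lengths(self):
        with pytest.raises(ValueError, match="150 samples.*200"):
            sp.compute_rms_windows(np.zeros((150, 2)), fs=2000,
                                   window_ms=100, step_ms=50)


class TestMuLaw:
    @pytest.mark.parametrize("mu", [255.0, float(2**20)])
    def test_fixed_points(self, mu):
        x = np.array([0.0, 1.0, -1.0])
        assert np.allclose(sp.mu_law_normalize(x, mu), x)

    def test_worked_values(self):
        assert np.isclose(sp.mu_law_normalize(np.array(0.5), 255.0), 0.87570,
                          atol=1e-4)
        assert np.isclose(sp.mu_law_normalize(np.array(0.001), float(2**20)),
                          0.50178, atol=1e-4)

    @pytest.mark.parametrize("mu", [255.0, float(2**20)])
    def test_strictly_increasing_and_odd(self, mu):
        x = np.linspace(-1, 1, 10001)
        y = sp.mu_law_normalize(x, mu)
        assert np.all(np.diff(y) > 0)
        assert np.allclose(y, -sp.mu_law_normalize(-x, mu))
        assert np.max(np.abs(y)) <= 1 + 1e-12

    def test_round_trip(self):
        x = np.linspace(-1, 1, 501)
        y = sp.mu_law_inverse(sp.mu_law_normalize(x, 2**20), 2**20)
        assert np.allclose(y, x, atol=1e-9)

    def test_small_mu_approaches_identity(self):
        x = np.linspace(-1, 1, 201)
        assert np.max(np.abs(sp.mu_law_normalize(x, 1e-6) - x)) < 0.01

    def test_out_of_range_reports_maximum(self):
        with pytest.raises(ValueError, match="1.5"):
            sp.mu_law_normalize(np.array([0.1, 1.5]), 255.0)
        with pytest.raises(ValueError):
            sp.mu_law_inverse(np.array([1.2]), 255.0)

    def test_inverse_endpoint(self):
        assert np.isclose(sp.mu_law_inverse(np.array(1.0), 255.0), 1.0)
        assert sp.mu_law_inverse(np.array(0.0), 255.0) == 0.0

    @given(mu=st.floats(min_value=1e-3, max_value=1e7))
    @settings(max_examples=30, deadline=None)
    def test_monotone_odd_for_any_mu(self, mu):
        x = np.linspace(-1, 1, 101)
        y = sp.mu_law_normalize(x, mu)
        assert np.all(np.diff(y) > 0)
        assert np.allclose(y + y[::-1], 0, atol=1e-12)


class TestZscore:
    def test_standardized_input_unchanged(self, rng):
        x = rng.normal(size=(200, 3))
        x = (x - x.mean(0)) / x.std(0)
        out = sp.zscore_normalize(x, np.zeros(3), np.ones(3))
        assert np.allclose(out, x)

    def test_fitted_mean_zero(self):
        x = np.array([2.0, 4.0, 6.0])[:, None]
        out = sp.zscore_normalize(x, np.array([4.0]), x.std(0))
        assert np.isclose(out.mean(), 0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(100, 1))
        y = 3.0 * x + 7.0
        zx = sp.zscore_normalize(x, x.mean(0), x.std(0))
        zy = sp.zscore_normalize(y, y.mean(0), y.std(0))
        assert np.allclose(zx, zy, atol=1e-10)

    def test_zero_std_names_channel(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            sp.zscore_normalize(np.ones((5, 2)), np.zeros(2),
                                np.array([1.0, 0.0]))


class TestResampleLabels:
    def test_constant_stays_constant(self):
        out = sp.resample_labels(np.full((20, 2), 33.0), 20, 2000)
        assert np.allclose(out, 33.0)

    def test_length_contract(self):
        out = sp.resample_labels(np.zeros((20, 1)), 20, 2000)
        assert out.shape[0] == 2000

    def test_linear_ramp_preserved(self):
        ramp = np.linspace(0, 10, 21)[:, None]
        out = sp.resample_labels(ramp, 20, 2000)
        t_out = np.arange(out.shape[0]) / 2000
        t_out = np.clip(t_out, 0, 1.0)
        assert np.allclose(out[:, 0], 10 * t_out, atol=1e-9)
        assert np.isclose(out[0, 0], 0) and np.isclose(out[-1, 0], 10, atol=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 label samples"):
            sp.resample_labels(np.zeros((1, 2)), 20, 2000)


class TestSplitTrials:
    def test_partition_shape_and_disjointness(self):
        train, test = sp.split_trials(range(1, 7), seed=3)
        assert len(train) == 4 and len(test) == 2
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(range(1, 7))

    def test_determinism(self):
        assert sp.split_trials(range(1, 7), seed=9) == sp.split_trials(range(1, 7), seed=9)

    def test_all_15_partitions_occur(self):
        seen = set()
        for seed in range(200):
            _, test = sp.split_trials(range(1, 7), seed=seed)
            seen.add(tuple(test))
        assert len(seen) == len(list(itertools.combinations(range(1, 7), 2)))

    def test_wrong_trial_count(self):
        with pytest.raises(ValueError, match="5"):
            sp.split_trials(range(1, 6), seed=0)


class TestPipeline:
    def test_feature_label_alignment_and_range(self, tiny_cohort):
        rec = tiny_cohort.recordings[0]
        norm = sp.fit_normalization([sp.raw_rms(rec)])
        fs = sp.prepare_features(rec, norm)
        assert fs.features.shape[0] == fs.labels.shape[0]
        assert fs.features.min() >= 0 and fs.features.max() <= 1
        assert fs.norm_hash == norm.digest()

    def test_prescale_clips_out_of_range_test_data(self, tiny_cohort):
        recs = tiny_cohort.recordings[:2]
        norm = sp.fit_normalization([sp.raw_rms(recs[0])])
        feats = sp.apply_normalization(10.0 * sp.raw_rms(recs[1]), norm)
        assert feats.max() <= 1.0

    def test_csv_round_trip(self, tiny_feature_series, tmp_path):
        fs = tiny_feature_series[0]
        sp.save_feature_series(fs, tmp_path / "rec")
        back = sp.load_feature_series(tmp_path / "rec")
        assert np.allclose(back.features, fs.features)
        assert np.allclose(back.labels, fs.labels)
        assert back.provenance == fs.provenance
        assert back.norm_hash == fs.norm_hash

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            sp.FeatureSeries(np.zeros((5, 12)), np.zeros((4, 10)),
                             100.0, 50.0, ("s", "m", 1))
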