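"""Synthetic-data generator: determinism, calibration, recoverability."""

import numpy as np
import pytest
from scipy import signal

from neurosrt import (
    CLEAN,
    SimulatedListener,
    SyntheticTrfParams,
    make_dataset,
    make_envelope,
    make_trf_kernel,
    simulate_eeg,
)
from neurosrt.lagged import LagWindow, build_lag_matrix, pearson_accuracy, ridge_fit


class TestMakeEnvelope:
    def test_deterministic_given_seed(self):
        a = make_envelope(20.0, seed=5)
        b = make_envelope(20.0, seed=5)
        assert np.array_equal(a.values, b.values)
        c = make_envelope(20.0, seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_sixty_seconds_gives_3840_samples(self):
        assert len(make_envelope(60.0, seed=0)) == 3840

    def test_spectral_centroid_in_pass_band(self):
        centroids = []
        for seed in range(100):
            env = make_envelope(20.0, seed=seed)
            f, p = signal.periodogram(env.values, fs=64.0)
            centroids.append(np.sum(f * p) / np.sum(p))
        c = np.mean(centroids)
        assert 1.0 <= c <= 8.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_envelope(5.0, seed=0)


class TestMakeTrfKernel:
    def test_latencies_equal_baseline_at_reference_snr(self):
        params = SyntheticTrfParams()
        k = make_trf_kernel(params, 0.0)
        t = np.arange(len(k)) / 64.0 * 1000.0
        for comp in params.components:
            # extremum of the summed kernel near the baseline latency
            win = (t > comp.latency0 - 20) & (t < comp.latency0 + 20)
            idx = np.argmax(np.sign(comp.amp0) * k[win])
            assert abs(t[win][idx] - comp.latency0) < 1000.0 / 64 + 1e-9

    def test_p2_latency_shifts_by_slope_per_db(self):
        params = SyntheticTrfParams()
        p2 = params.components[2]
        assert p2.latency(1.0) - p2.latency(0.0) == pytest.approx(-6.001)
        assert p2.latency(4.0) == pytest.approx(p2.latency0 - 4 * 6.001)

    def test_isolated_component_peaks_at_its_amplitude(self):
        from neurosrt.simulate import TrfComponent

        params = SyntheticTrfParams(
            components=(
                TrfComponent("P1", 0.4, 50.0, 20.0, 0.0, 0.0),
                TrfComponent("N1", -1e-9, 120.0, 25.0, 0.0, 0.0),
                TrfComponent("P2", 1e-9, 200.0, 35.0, 0.0, 0.0),
            ),
            rate=1000.0,  # 1 ms lag grid hits the latency exactly
        )
        k = make_trf_kernel(params, 0.0)
        assert k[50] == pytest.approx(0.4, abs=1e-6)

    def test_latency_order_inversion_rejected(self):
        with pytest.raises(ValueError, match="order"):
            make_trf_kernel(SyntheticTrfParams(), 25.0)  # P2 would cross N1

    def test_clean_maps_to_shortest_latencies(self):
        params = SyntheticTrfParams()
        k_clean = make_trf_kernel(params, CLEAN)
        k_high = make_trf_kernel(params, 4.0)
        t = np.arange(len(k_clean)) / 64.0 * 1000.0
        assert t[np.argmax(k_clean[t > 100])] <= t[np.argmax(k_high[t > 100])]


class TestSimulateEeg:
    @staticmethod
    def _small_topo(n=8):
        topo = np.linspace(1.0, 0.2, n)
        return topo / np.linalg.norm(topo)

    def test_noise_free_channels_equal_convolution(self):
        listener = SimulatedListener(srt_true=-5.0)
        env = make_envelope(15.0, seed=1)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        topo = self._small_topo()
        trial = simulate_eeg(env, k, listener, CLEAN, noise_level=0.0, seed=2, topography=topo)
        conv = np.convolve(env.values, k)[: len(env.values)]
        assert np.allclose(trial.data, np.outer(topo, conv))

    def test_noise_free_trial_decodes_near_perfectly(self):
        listener = SimulatedListener(srt_true=-5.0)
        env = make_envelope(20.0, seed=3)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        trial = simulate_eeg(
            env, k, listener, CLEAN, noise_level=0.0, seed=4, topography=self._small_topo()
        )
        # the standard decision window cannot fully invert a kernel that
        # extends to 400 ms; a window covering the kernel support can
        window = LagWindow(-100, 350, 64)
        X = build_lag_matrix(trial.data, window)
        model = ridge_fit(X, env.values, 1e-4, window=window, n_channels=8)
        assert pearson_accuracy(model.predict(trial.data), env.values) > 0.98
        wide = LagWindow(-100, 500, 64)
        Xw = build_lag_matrix(trial.data, wide)
        model_w = ridge_fit(Xw, env.values, 1e-4, window=wide, n_channels=8)
        assert pearson_accuracy(model_w.predict(trial.data), env.values) > 0.99

    def test_zero_gain_gives_chance_level_decoding(self):
        # with g = 0 the channels are pure noise: expected accuracy ~ 0
        listener = SimulatedListener(srt_true=0.0, gain_slope=10.0)
        window = LagWindow(-100, 350, 64)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        topo = self._small_topo()

        env_tr = make_envelope(15.0, seed=10)
        tr = simulate_eeg(env_tr, k, listener, 50.0, noise_level=1.0, seed=11, topography=topo)
        X = build_lag_matrix(tr.data, window)
        model = ridge_fit(X, env_tr.values, 100.0, window=window, n_channels=8)

        rs = []
        for s in range(50):
            env = make_envelope(15.0, seed=1000 + s)
            trial = simulate_eeg(
                env, k, listener, -60.0, noise_level=1.0, seed=2000 + s, topography=topo
            )  # g(-60) ~ 0
            rs.append(pearson_accuracy(model.predict(trial.data), env.values))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-3

    def test_more_noise_lowers_decoding_accuracy(self):
        listener = SimulatedListener(srt_true=-5.0)
        window = LagWindow(-100, 350, 64)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        topo = self._small_topo()

        def mean_r(noise):
            rs = []
            for s in range(50):
                env = make_envelope(15.0, seed=100 + s)
                trial = simulate_eeg(
                    env, k, listener, CLEAN, noise_level=noise, seed=500 + s, topography=topo
                )
                X = build_lag_matrix(trial.data, window)
                model = ridge_fit(X, env.values, 100.0, window=window, n_channels=8)
                rs.append(pearson_accuracy(model.predict(trial.data), env.values))
            return np.mean(rs)

        assert mean_r(2.0) > mean_r(4.0)

    def test_negative_noise_rejected(self):
        env = make_envelope(15.0, seed=0)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        with pytest.raises(ValueError):
            simulate_eeg(env, k, SimulatedListener(), CLEAN, noise_level=-1.0)

    def test_deterministic_given_seed(self):
        env = make_envelope(15.0, seed=0)
        k = make_trf_kernel(SyntheticTrfParams(), 0.0)
        topo = self._small_topo()
        a = simulate_eeg(env, k, SimulatedListener(), -5.0, 2.0, seed=9, topography=topo)
        b = simulate_eeg(env, k, SimulatedListener(), -5.0, 2.0, seed=9, topography=topo)
        assert np.array_equal(a.data, b.data)


class TestSentenceResponse:
    def test_midpoint_probability_exactly_half(self):
        listener = SimulatedListener(srt_true=-5.0, word_slope=0.5)
        assert listener.word_probability(-5.0) == 0.5
        rng = np.random.default_rng(0)
        scores = [
            listener.simulate_sentence_response(-5.0, rng=rng) for _ in range(10_000)
        ]
        assert np.mean(scores) == pytest.approx(2.5, abs=0.05)

    def test_saturation_far_above_threshold(self):
        listener = SimulatedListener(srt_true=-5.0, word_slope=0.5)
        rng = np.random.default_rng(1)
        scores = [
            listener.simulate_sentence_response(200.0, rng=rng) for _ in range(100)
        ]
        assert all(s == 5 for s in scores)

    def test_binomial_mean_from_logistic(self):
        # word_slope 0.5/dB at srt_true + 2: p = expit(1) ~ 0.731 -> mean ~ 3.66
        listener = SimulatedListener(srt_true=-5.0, word_slope=0.5)
        rng = np.random.default_rng(2)
        scores = [
            listener.simulate_sentence_response(-3.0, rng=rng) for _ in range(10_000)
        ]
        from scipy.special import expit

        assert np.mean(scores) == pytest.approx(5 * expit(1.0), abs=0.05)

    def test_psychometric_calibration_within_binomial_ci(self):
        listener = SimulatedListener(srt_true=-2.0, word_slope=0.8)
        rng = np.random.default_rng(3)
        n = 20_000
        total = sum(
            listener.simulate_sentence_response(-2.0, n_words=1, rng=rng)
            for _ in range(n)
        )
        phat = total / n
        assert abs(phat - 0.5) < 3 * np.sqrt(0.25 / n)


class TestMakeDataset:
    def test_default_structure_has_96_trials(self, montage):
        # structural check at short duration: 16 trials x (5 SNR + clean)
        ds = make_dataset(
            SimulatedListener(), n_trials_per_condition=16, seed=0, duration=10.0,
            montage=montage,
        )
        assert len(ds.trials) == 96
        assert len(ds.conditions) == 6
        for cond in ds.conditions:
            assert len(ds.by_condition(cond)) == 16

    def test_two_per_condition_gives_12(self, montage):
        ds = make_dataset(
            SimulatedListener(), n_trials_per_condition=2, seed=0, duration=10.0,
            montage=montage,
        )
        assert len(ds.trials) == 12

    def test_different_seeds_share_no_trial(self, montage):
        a = make_dataset(SimulatedListener(), n_trials_per_condition=2, seed=1, duration=10.0, montage=montage)
        b = make_dataset(SimulatedListener(), n_trials_per_condition=2, seed=2, duration=10.0, montage=montage)
        for ta, tb in zip(a.trials, b.trials):
            assert not np.array_equal(ta.data, tb.data)

    def test_ground_truth_attached(self, montage):
        ds = make_dataset(SimulatedListener(srt_true=-4.0), n_trials_per_condition=2, seed=3, duration=10.0, montage=montage)
        gt = ds.ground_truth
        assert gt["srt_true"] == -4.0
        assert len(gt["components"]) == 3
        assert len(gt["topography"]) == 64

    def test_round_trip_through_hdf5(self, tmp_path, montage):
        from neurosrt import load_dataset, save_dataset

        ds = make_dataset(SimulatedListener(), n_trials_per_condition=2, seed=4, duration=10.0, montage=montage)
        path = str(tmp_path / "ds.h5")
        save_dataset(ds, path)
        loaded = load_dataset(path)
        assert len(loaded.trials) == len(ds.trials)
        for a, b in zip(ds.trials, loaded.trials):
            assert np.array_equal(a.data, b.data)
            assert a.condition == b.condition
            assert np.array_equal(a.envelope, b.envelope)
        assert loaded.ground_truth["srt_true"] == ds.ground_truth["srt_true"]
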