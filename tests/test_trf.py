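"""Forward-model TRF analysis: encoder, deflection fits, mixed model."""

import numpy as np
import pandas as pd
import pytest

from neurosrt.containers import CLEAN, condition_key
from neurosrt.trf import (
    DEFLECTION_BOUNDS,
    ENCODER_LAMBDA,
    TrfEstimate,
    encoder_significance_gate,
    fit_deflections,
    fit_encoder,
    grand_average_trf,
    lmm_snr_effects,
    select_channels,
)


@pytest.fixture(scope="module")
def encoder_estimates(small_dataset):
    return fit_encoder(small_dataset)


class TestFitEncoder:
    def test_lambda_fixed_at_100_everywhere(self, encoder_estimates):
        assert all(est.lam == ENCODER_LAMBDA for est in encoder_estimates.values())

    def test_kernel_shape(self, encoder_estimates, small_dataset):
        est = next(iter(encoder_estimates.values()))
        assert est.kernels.shape == (64, 39)  # channels x lags (-100..500 ms)

    def test_noise_free_ground_truth_recovery(self, noise_free_dataset):
        # encoder kernels correlate > 0.99 with the generating kernel per channel
        from neurosrt.simulate import SyntheticTrfParams, make_trf_kernel

        gt = noise_free_dataset.ground_truth
        topo = np.asarray(gt["topography"])
        ests = fit_encoder(noise_free_dataset)
        base = SyntheticTrfParams()
        for cond in noise_free_dataset.conditions:
            offset = CLEAN if cond == CLEAN else float(cond) - gt["srt_center"]
            kernel = make_trf_kernel(base, offset)
            est = ests[condition_key(cond)]
            times = est.lag_times_ms
            support = (times >= 0) & (times <= 400)  # the generating kernel's lag span
            true_on_lags = np.interp(
                times[support], np.arange(len(kernel)) / 64 * 1000, kernel
            )
            for ch in range(0, 64, 13):
                r = np.corrcoef(est.kernels[ch][support], topo[ch] * true_on_lags)[0, 1]
                assert r > 0.99

    def test_too_few_trials_rejected(self, small_dataset):
        from neurosrt.containers import EegDataset

        one_each = EegDataset(
            trials=[small_dataset.by_condition(c)[0] for c in small_dataset.conditions],
            channel_labels=small_dataset.channel_labels,
            rate=small_dataset.rate,
            conditions=small_dataset.conditions,
        )
        with pytest.raises(ValueError, match="leave-one-out"):
            fit_encoder(one_each)


class TestSelectChannels:
    def test_concentrates_on_high_gain_channels(self, encoder_estimates, small_dataset):
        topo = np.asarray(small_dataset.ground_truth["topography"])
        chosen = select_channels([encoder_estimates], small_dataset.channel_labels, k=17)
        top_quartile = {
            small_dataset.channel_labels[i] for i in np.argsort(np.abs(topo))[-16:]
        }
        overlap = len(top_quartile & set(chosen))
        assert overlap >= 10

    def test_k_equal_to_all_channels(self, encoder_estimates, small_dataset):
        chosen = select_channels([encoder_estimates], small_dataset.channel_labels, k=64)
        assert set(chosen) == set(small_dataset.channel_labels)

    def test_k_zero_rejected(self, encoder_estimates, small_dataset):
        with pytest.raises(ValueError):
            select_channels([encoder_estimates], small_dataset.channel_labels, k=0)


class TestEncoderGate:
    def test_informative_conditions_included(self, encoder_estimates, small_dataset):
        channels = select_channels([encoder_estimates], small_dataset.channel_labels, 17)
        gate = encoder_significance_gate(
            encoder_estimates, small_dataset, channels, n_mismatch=12, seed=0
        )
        assert gate["clean"]["included"]
        # the highest-SNR noise condition is also strongly driven
        top = condition_key(max(small_dataset.noise_conditions))
        assert gate[top]["included"]


class TestFitDeflections:
    @staticmethod
    def _times():
        return np.arange(-6, 33) / 64 * 1000

    def test_exact_gaussian_recovered(self):
        t = self._times()
        y = -0.05 * np.exp(-(((t - 120) / 30) ** 2))
        fits = {f.component: f for f in fit_deflections(y, t)}
        n1 = fits["N1"]
        assert n1.r_squared > 0.999
        assert not n1.excluded
        assert n1.p == pytest.approx(-0.05, rel=1e-3)
        assert n1.l == pytest.approx(120, abs=0.5)
        assert n1.w == pytest.approx(30, rel=0.05)

    def test_noisy_recovery_within_tolerances(self):
        t = self._times()
        rng = np.random.default_rng(0)
        lat_err, amp_err = [], []
        for _ in range(100):
            y = 0.05 * np.exp(-(((t - 45) / 20) ** 2))
            y = y + 0.005 * rng.standard_normal(len(t))  # 10% of |p|
            f = {f.component: f for f in fit_deflections(y, t)}["P1"]
            lat_err.append(abs(f.l - 45))
            amp_err.append(abs(f.p - 0.05) / 0.05)
        assert np.median(lat_err) < 5.0
        assert np.median(amp_err) < 0.15

    def test_flat_trf_excluded(self):
        t = self._times()
        fits = fit_deflections(np.zeros_like(t), t)
        assert all(f.excluded for f in fits)

    def test_bounds_never_violated(self):
        t = self._times()
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.standard_normal(len(t)) * 0.1
            for f in fit_deflections(y, t):
                bnd = DEFLECTION_BOUNDS[f.component]
                assert bnd["p"][0] - 1e-9 <= f.p <= bnd["p"][1] + 1e-9
                assert bnd["l"][0] - 1e-9 <= f.l <= bnd["l"][1] + 1e-9
                assert f.w <= bnd["w"][1] + 1e-9

    def test_latency_pinned_to_bound_flagged(self):
        t = self._times()
        # monotone ramp in the N1 window pushes the optimum to a boundary
        y = -np.clip((t - 60) / 100, 0, None)
        f = {f.component: f for f in fit_deflections(y, t)}["N1"]
        if f.at_bound:
            assert np.isclose(f.l, 70.0) or np.isclose(f.l, 150.0)


class TestLmm:
    @staticmethod
    def _table(slope_lat, slope_amp, n_participants=15, noise=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            offs_lat = rng.normal(0, 2.0)
            offs_amp = rng.normal(0, 0.01)
            for snr in (-4, -2, 0, 2, 4):
                for comp, base_l, base_a in (("P1", 50, 0.4), ("N1", 120, -0.5), ("P2", 200, 0.6)):
                    rows.append(
                        {
                            "participant_id": f"p{p}",
                            "snr_rel": float(snr),
                            "component": comp,
                            "latency": base_l + offs_lat + slope_lat * snr + noise * rng.standard_normal(),
                            "amplitude": base_a + offs_amp + slope_amp * snr + 0.005 * rng.standard_normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_six_rows_and_holm_flags(self):
        out = lmm_snr_effects(self._table(-2.0, 0.01))
        assert len(out) == 6
        assert set(out["component"]) == {"P1", "N1", "P2"}
        assert out["holm_significant"].dtype == bool

    def test_recovers_generating_slopes_within_2_se(self):
        out = lmm_snr_effects(self._table(-2.0, 0.01, seed=3))
        lat = out[(out["feature"] == "latency")]
        for _, row in lat.iterrows():
            assert abs(row["coefficient"] - (-2.0)) < 2 * row["std_error"]
        amp = out[(out["feature"] == "amplitude")]
        for _, row in amp.iterrows():
            assert abs(row["coefficient"] - 0.01) < 2 * row["std_error"]

    def test_null_slopes_rarely_significant(self):
        out = lmm_snr_effects(self._table(0.0, 0.0, seed=5))
        assert out["holm_significant"].sum() <= 1

    def test_insufficient_participants_marked(self):
        table = self._table(-2.0, 0.01, n_participants=2)
        out = lmm_snr_effects(table)
        assert (~out["estimable"]).all()


class TestGrandAverage:
    def test_single_participant_identity_and_window(self, encoder_estimates, small_dataset):
        channels = select_channels([encoder_estimates], small_dataset.channel_labels, 17)
        ga = grand_average_trf([encoder_estimates], channels, small_dataset.channel_labels)
        assert ga["tau_ms"].max() <= 400.0
        assert ga["tau_ms"].min() >= -100.0
        ch_idx = [small_dataset.channel_labels.index(c) for c in channels]
        est = encoder_estimates["clean"]
        keep = (est.lag_times_ms >= -100) & (est.lag_times_ms <= 400)
        expected = est.kernels[ch_idx].mean(axis=0)[keep]
        got = ga[ga["condition"] == "clean"]["weight"].to_numpy()
        assert np.allclose(got, expected)

    def test_component_ordering_visible_at_mid_snr(self, encoder_estimates, small_dataset):
        channels = select_channels([encoder_estimates], small_dataset.channel_labels, 17)
        ga = grand_average_trf([encoder_estimates], channels, small_dataset.channel_labels)
        mid = condition_key(sorted(small_dataset.noise_conditions)[2])
        sub = ga[ga["condition"] == mid]
        t = sub["tau_ms"].to_numpy()
        w = sub["weight"].to_numpy()
        # P1 peak before the N1 trough before the P2 peak
        t_p1 = t[(t >= 0) & (t <= 100)][np.argmax(w[(t >= 0) & (t <= 100)])]
        t_n1 = t[(t >= 70) & (t <= 160)][np.argmin(w[(t >= 70) & (t <= 160)])]
        t_p2 = t[(t >= 150) & (t <= 300)][np.argmax(w[(t >= 150) & (t <= 300)])]
        assert t_p1 < t_n1 < t_p2
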