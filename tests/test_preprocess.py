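"""Oracles for every preprocessing step, plus end-to-end chain invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlaspd import optics
from atlaspd.design import BlockDesign
from atlaspd.preprocess import (
    baseline_correct,
    beer_lambert_invert,
    build_dataset,
    butter_lowpass,
    impute_missing,
    intensity_to_od,
    iqr_outlier_clip,
    savgol_smooth,
    scalp_coupling_index,
    signal_quality_index,
    spline_wavelet_correct,
    tddr_correct,
    zscore_channels,
)
from atlaspd.synthgen import GroupEffectProfile, NoiseProfile, simulate_cohort


class TestOpticalDensity:
    def test_reference_intensity_gives_zero_od(self):
        x = np.full(100, 2.5)
        np.testing.assert_allclose(intensity_to_od(x), 0.0, atol=1e-12)

    def test_tenth_of_reference_gives_od_one(self):
        ref = np.ones(50)
        x = np.full(50, 0.1)
        od = intensity_to_od(x, reference=ref)
        np.testing.assert_allclose(od, 1.0, rtol=1e-12)

    def test_matches_elementwise_log_ratio_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, size=200)
        od = intensity_to_od(x)
        np.testing.assert_allclose(od, -np.log10(x / x.mean()), rtol=1e-12)

    def test_nonpositive_flagged_as_missing_not_inf(self):
        x = np.array([1.0, 0.0, -2.0, 1.0])
        od = intensity_to_od(x)
        assert np.isnan(od[1]) and np.isnan(od[2])
        assert np.isfinite(od[[0, 3]]).all()


class TestBeerLambert:
    def test_zero_od_gives_zero_concentrations(self):
        od = np.zeros((4, 100, 2))
        hemo = beer_lambert_invert(od)
        np.testing.assert_allclose(hemo.concentrations, 0.0)

    def test_forward_then_invert_recovers_exactly(self):
        rng = np.random.default_rng(1)
        hbo = rng.normal(0, 0.5, size=(3, 50))
        hbr = rng.normal(0, 0.2, size=(3, 50))
        od = optics.hemoglobin_to_od(hbo, hbr, dpf=6.0, distance_cm=3.0)
        hemo = beer_lambert_invert(od, dpf=6.0, distance_cm=3.0)
        np.testing.assert_allclose(hemo.hbo, hbo, atol=1e-12)
        np.testing.assert_allclose(hemo.hbr, hbr, atol=1e-12)
        np.testing.assert_allclose(hemo.hbt, hbo + hbr, atol=1e-12)

    def test_single_sample_matches_manual_2x2_solve(self):
        od = np.array([[0.01, 0.02]])
        e = optics.extinction_matrix() * 18.0  # dpf 6 * 3 cm
        expected = np.linalg.solve(e, od[0])
        hemo = beer_lambert_invert(od)
        assert hemo.hbo[0] == pytest.approx(expected[0], rel=1e-12)
        assert hemo.hbr[0] == pytest.approx(expected[1], rel=1e-12)

    def test_hbt_is_sum_everywhere(self, small_cohort):
        from atlaspd.preprocess import preprocess_subject
        hemo = preprocess_subject(small_cohort[0])
        np.testing.assert_allclose(hemo.hbt, hemo.hbo + hemo.hbr, atol=1e-9)


class TestTDDR:
    def test_linear_ramp_passthrough(self):
        x = np.linspace(0, 1, 500)
        np.testing.assert_allclose(tddr_correct(x), x, atol=1e-9)

    def test_spike_residual_below_20_percent(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 1000) + 0.01 * rng.standard_normal(1000)
        spike = 10 * 0.01 * 3  # 10 robust sds of the derivative scale
        y = x.copy()
        y[500] += spike
        out = tddr_correct(y)
        assert abs(out[500] - x[500]) < 0.2 * spike

    def test_second_application_changes_little(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 0.01, 800))
        x[200] += 0.5
        once = tddr_correct(x)
        twice = tddr_correct(once)
        first_pass = np.abs(once - x).max()
        assert np.abs(twice - once).max() < 0.01 * first_pass + 1e-12

    def test_constant_series_unchanged(self):
        x = np.full(100, 3.14)
        np.testing.assert_array_equal(tddr_correct(x), x)


class TestSplineWavelet:
    def test_unflagged_white_noise_untouched(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1000) * 0.1
        out = spline_wavelet_correct(x, 10.0, segments=np.zeros(1000, bool))
        assert np.corrcoef(x, out)[0, 1] > 0.99

    def test_step_artifact_reduced(self):
        rng = np.random.default_rng(5)
        x = 0.01 * rng.standard_normal(1000)
        amp = 1.0
        x[500:] += amp
        out = spline_wavelet_correct(x, 10.0)
        step_after = out[520:560].mean() - out[440:480].mean()
        assert abs(step_after) < 0.3 * amp

    def test_all_zeros_passthrough(self):
        x = np.zeros(512)
        np.testing.assert_allclose(spline_wavelet_correct(x, 10.0), 0.0)

    def test_short_series_passthrough_with_warning(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="wavelet"):
            out = spline_wavelet_correct(x, 10.0)
        np.testing.assert_array_equal(out, x)


class TestSCI:
    def test_identical_series_score_one(self):
        rng = np.random.default_rng(6)
        t = np.arange(4000) / 10.0
        x = 1 + 0.01 * np.sin(2 * np.pi * 1.1 * t) + 0.001 * rng.standard_normal(4000)
        assert scalp_coupling_index(x, x, 10.0) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(84_000)
        b = rng.standard_normal(84_000)
        assert abs(scalp_coupling_index(a, b, 100.0)) < 0.05

    def test_shared_cardiac_high_score(self):
        rng = np.random.default_rng(8)
        t = np.arange(8400) / 10.0
        card = np.sin(2 * np.pi * 1.1 * t)
        a = 1 + 0.01 * card + 0.001 * rng.standard_normal(len(t))
        b = 1 + 0.008 * card + 0.001 * rng.standard_normal(len(t))
        assert scalp_coupling_index(a, b, 10.0) > 0.9

    def test_degenerate_series_scores_zero(self):
        assert scalp_coupling_index(np.ones(1000), np.ones(1000), 10.0) == 0.0


class TestSQI:
    def test_flatlined_channel_below_threshold(self):
        assert signal_quality_index(np.ones(8400), 10.0) < 2.5

    def test_clean_cardiac_channel_above_threshold(self):
        rng = np.random.default_rng(9)
        t = np.arange(8400) / 10.0
        x = 1 + 0.01 * np.sin(2 * np.pi * 1.1 * t) + 0.002 * rng.standard_normal(len(t))
        assert signal_quality_index(x, 10.0) > 2.5

    def test_adding_spikes_never_raises_score(self):
        rng = np.random.default_rng(10)
        t = np.arange(8400) / 10.0
        x = 1 + 0.01 * np.sin(2 * np.pi * 1.1 * t) + 0.002 * rng.standard_normal(len(t))
        scores = []
        for n_spikes in (0, 5, 20, 60):
            y = x.copy()
            pos = rng.integers(0, len(y), size=n_spikes)
            y[pos] += 0.5
            scores.append(signal_quality_index(y, 10.0))
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))


class TestButterworth:
    def test_constant_series_unchanged(self):
        x = np.full(2000, 1.7)
        np.testing.assert_allclose(butter_lowpass(x, 0.1, 4, 10.0), x, atol=1e-9)

    def test_1hz_probe_attenuated_99_percent(self):
        t = np.arange(60_000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butter_lowpass(x, 0.1, 4, 100.0)
        assert np.sqrt(np.mean(y ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_deep_passband_preserved(self):
        t = np.arange(200_000) / 100.0
        x = np.sin(2 * np.pi * 0.01 * t)
        y = butter_lowpass(x, 0.1, 4, 100.0)
        core = slice(20_000, -20_000)  # ignore filter edge transients
        assert np.sqrt(np.mean(y[core] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[core] ** 2)), rel=0.02)

    def test_zero_phase_on_passband_probe(self):
        t = np.arange(84_000) / 100.0
        x = np.sin(2 * np.pi * 0.02 * t)
        y = butter_lowpass(x, 0.1, 4, 100.0)
        lag = np.argmax(np.correlate(y[2000:-2000], x[2000:-2000], "same"))
        assert lag == len(x[2000:-2000]) // 2

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butter_lowpass(np.zeros(100), cutoff_hz=6.0, sampling_hz=10.0)


class TestBaselineSavgolZscore:
    def test_pre_task_mean_removed(self, design_10hz):
        rng = np.random.default_rng(11)
        x = 5.0 + rng.standard_normal(design_10hz.n_samples)
        y = baseline_correct(x, design_10hz)
        n0 = int(10 * design_10hz.sampling_hz)
        assert abs(y[:n0].mean()) < 1e-12
        np.testing.assert_allclose(y, x - x[:n0].mean(), atol=1e-12)

    def test_constant_series_becomes_zero(self, design_10hz):
        y = baseline_correct(np.full(design_10hz.n_samples, 2.0), design_10hz)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_savgol_exact_on_cubic(self):
        t = np.linspace(0, 1, 101)
        x = 2 * t ** 3 - t ** 2 + 0.5 * t - 1
        y = savgol_smooth(x, polyorder=3, window=5)
        np.testing.assert_allclose(y[2:-2], x[2:-2], atol=1e-9)

    def test_savgol_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(50), polyorder=3, window=4)

    def test_zscore_moments(self):
        rng = np.random.default_rng(12)
        x = rng.normal(3.0, 2.0, size=(4, 5, 300))
        z = zscore_channels(x)
        assert np.abs(z.mean(axis=-1)).max() < 1e-9
        assert np.abs(z.std(axis=-1) - 1).max() < 1e-9

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(13)
        z1 = zscore_channels(rng.standard_normal((2, 3, 100)))
        np.testing.assert_allclose(zscore_channels(z1), z1, atol=1e-9)

    def test_zscore_constant_channel_zeroed_and_flagged(self):
        x = np.ones((1, 2, 50))
        x[0, 1] = np.arange(50)
        z, flags = zscore_channels(x, return_flags=True)
        np.testing.assert_array_equal(z[0, 0], 0.0)
        assert flags[0, 0] and not flags[0, 1]


class TestIQRAndImputation:
    def test_single_outlier_flagged_on_ten_point_set(self):
        x = np.r_[np.arange(1.0, 10.0), 100.0]
        clipped, mask = iqr_outlier_clip(x, k=1.5)
        assert mask.sum() == 1 and mask[-1]
        q1, q3 = np.percentile(x, [25, 75])
        assert clipped[-1] == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_all_equal_no_flags(self):
        _, mask = iqr_outlier_clip(np.full(20, 7.0), k=1.5)
        assert mask.sum() == 0

    @given(st.floats(min_value=0.5, max_value=5.0))
    @settings(max_examples=20, deadline=None)
    def test_flag_count_non_increasing_in_k(self, k):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(500)
        _, m1 = iqr_outlier_clip(x, k=k)
        _, m2 = iqr_outlier_clip(x, k=k + 0.5)
        assert m2.sum() <= m1.sum()

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((2, 4, 100))
        out, excl = impute_missing(x, seed=0)
        np.testing.assert_array_equal(out, x)
        assert not excl.any()

    def test_common_mode_sample_recovered(self):
        # channels share a strong common component: one masked sample is
        # recoverable from the other channels at that time point
        rng = np.random.default_rng(16)
        common = np.sin(np.linspace(0, 8 * np.pi, 400)) * 5
        x = common[None, :] + 0.01 * rng.standard_normal((6, 400))
        x = x[None]  # one subject
        truth = x[0, 2, 200]
        x[0, 2, 200] = np.nan
        out, _ = impute_missing(x, seed=1)
        assert abs(out[0, 2, 200] - truth) < 0.01 * max(1.0, abs(truth))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((1, 4, 200))
        x[0, 1, 50:60] = np.nan
        a, _ = impute_missing(x.copy(), seed=7)
        b, _ = impute_missing(x.copy(), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_mostly_missing_channel_excluded(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal((1, 3, 100))
        x[0, 0, :60] = np.nan
        _, excl = impute_missing(x, seed=0)
        assert excl[0, 0] and not excl[0, 1:].any()


class TestBuildDataset:
    def test_shapes_and_normalization(self, small_dataset):
        assert small_dataset.data.shape == (6, 22, 840)
        assert small_dataset.normalized
        assert not np.isnan(small_dataset.data).any()
        sd = small_dataset.data.std(axis=-1)
        live = ~small_dataset.excluded
        assert np.abs(sd[live] - 1).max() < 1e-6

    def test_provenance_records_chain_order(self, small_dataset):
        prov = " > ".join(small_dataset.provenance)
        order = ["OD", "TDDR", "wavelet", "quality", "lowpass", "MBLL",
                 "baseline", "savgol", "decimate", "IQR", "z-score"]
        pos = [prov.find(step) for step in order]
        assert all(p >= 0 for p in pos)
        assert pos == sorted(pos)

    def test_target_hz_one_gives_840_steps(self, small_dataset):
        assert small_dataset.sampling_hz == 1.0
        assert small_dataset.data.shape[-1] == 840

    def test_noiseless_chain_recovers_block_amplitudes(self, noiseless_cohort,
                                                       design_10hz):
        """End-to-end: with z-scoring disabled and gating off, the processed
        HbO reproduces injected block-evoked amplitudes within 5%."""
        from scipy.signal import fftconvolve

        from atlaspd.synthgen import make_hrf

        ds = build_dataset(noiseless_cohort, chromophore="hbo", target_hz=10.0,
                           zscore=False, sqi_threshold=0.0, sci_threshold=-1.1)
        hrf = make_hrf(sampling_hz=10.0)
        task, rest = design_10hz.task_mask(), design_10hz.rest_mask()
        lat = {"HC": 0.0, "HY1": 1.0, "HY2": 3.5}
        for rec, row, lab in zip(noiseless_cohort, ds.data, ds.labels):
            box = design_10hz.boxcar()
            s = int(round(lat[lab] * 10))
            box = np.concatenate([np.zeros(s), box[:len(box) - s]])
            evoked = fftconvolve(box, hrf)[:design_10hz.n_samples] / hrf.sum()
            gain = evoked[task].mean() - evoked[rest].mean()
            est = row[:, task].mean(axis=1) - row[:, rest].mean(axis=1)
            expected = rec.ground_truth_amp_um * gain
            np.testing.assert_allclose(est, expected, rtol=0.05)

    def test_bad_channel_is_gated_and_refilled(self, design_10hz):
        noise = NoiseProfile(cardiac_amp_um=0.03, respiratory_amp_um=0.02,
                             mayer_amp_um=0.02, drift_scale_um=0.004,
                             white_sd_um=0.03, motion_rate_per_min=0.2,
                             bad_channel_p=0.4)
        cohort = simulate_cohort(1, design=design_10hz,
                                 effects=GroupEffectProfile.high_snr(),
                                 noise=noise, seed=21)
        ds = build_dataset(cohort, target_hz=1.0, seed=21)
        assert ds.excluded.any()
        assert not np.isnan(ds.data).any()

    def test_unknown_chromophore_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="chromophore"):
            build_dataset(small_cohort, chromophore="melanin")
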