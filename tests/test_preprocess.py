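import numpy as np
import pytest
from scipy.signal import periodogram

from conftest import make_channel, make_recording
from slowwave.data import AnalysisConfig, EpochSpec
from slowwave.errors import DataError
from slowwave.preprocess import (derive_channels, despike_moving_sd,
                                 detect_threshold_artifacts,
                                 preprocess_recording, repair_by_interpolation,
                                 synchronize, wavelet_denoise)

BASELINE = (0.0, 100.0)


def _mabp(values, rate=1.0):
    return make_channel("MABP", values, rate=rate)


class TestThresholdDetection:
    def test_brief_20pct_excursion_flagged(self):
        v = np.full(600, 50.0)
        v[300:305] = 60.0  # 20% for 5 s
        mask = detect_threshold_artifacts(_mabp(v), BASELINE, 0.15)
        assert mask.flags[300:305].all()
        assert mask.flags.sum() == 5
        assert mask.provenance == "threshold-rule"

    def test_sustained_step_not_flagged(self):
        v = np.full(600, 50.0)
        v[300:] = 60.0  # consistent change to the end of the epoch
        mask = detect_threshold_artifacts(_mabp(v), BASELINE, 0.15)
        assert not mask.flags.any()

    def test_subthreshold_excursion_ignored(self):
        v = np.full(600, 50.0)
        v[300:305] = 55.0  # 10%
        mask = detect_threshold_artifacts(_mabp(v), BASELINE, 0.15)
        assert not mask.flags.any()

    def test_nonpositive_baseline_errors(self):
        v = np.zeros(600)
        with pytest.raises(DataError, match="baseline"):
            detect_threshold_artifacts(_mabp(v), BASELINE, 0.15)

    def test_recall_on_injected_artifacts(self):
        # 30%-magnitude transients; scaled-down version of the acceptance
        # run (full 200-seed sweep lives in test_acceptance.py)
        from slowwave.simulate import inject_artifacts
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = 50.0 + 1.0 * np.sin(2 * np.pi * 0.01 * np.arange(3600.0)) \
                + 0.3 * rng.standard_normal(3600)
            chan, pos = inject_artifacts(_mabp(v), 6.0, 0.30, (2.0, 15.0), seed)
            mask = detect_threshold_artifacts(chan, BASELINE, 0.15)
            for start, stop in pos:
                total += stop - start
                hits += int(mask.flags[start:stop].sum())
        assert total > 0
        assert hits / total >= 0.95


class TestRepair:
    def test_linear_repair_restores_straight_line(self):
        v = np.arange(50.0)
        flags = np.zeros(50, bool)
        flags[20] = True
        broken = _mabp(v.copy())
        broken.values[20] = 999.0
        fixed = repair_by_interpolation(broken, flags, "linear")
        assert fixed.values[20] == pytest.approx(20.0, abs=1e-12)

    def test_identity_on_empty_mask(self, rng):
        v = 50 + rng.standard_normal(64)
        ch = _mabp(v)
        out = repair_by_interpolation(ch, np.zeros(64, bool), "linear")
        np.testing.assert_array_equal(out.values, ch.values)

    def test_all_true_mask_errors(self):
        with pytest.raises(DataError, match="entire"):
            repair_by_interpolation(_mabp(np.ones(10)), np.ones(10, bool))

    def test_spline_repair_beats_local_polynomial_oracle_bound(self):
        # oracle: independent cubic polyfit over the 8 nearest good samples
        t = np.arange(200.0)
        clean = np.sin(2 * np.pi * 0.02 * t)
        flags = np.zeros(200, bool)
        flags[[60, 61, 62]] = True
        broken = _mabp(clean.copy())
        broken.values[flags] = 5.0
        fixed = repair_by_interpolation(broken, flags, "spline")
        good = ~flags
        near = slice(54, 70)
        coef = np.polyfit(t[near][good[near]], clean[near][good[near]], 3)
        oracle_err = np.max(np.abs(np.polyval(coef, t[flags]) - clean[flags]))
        spline_err = np.max(np.abs(fixed.values[flags] - clean[flags]))
        assert spline_err <= oracle_err + 1e-9


class TestDespike:
    def test_single_spike_on_constant_flagged_and_removed(self):
        v = np.full(100, 10.0)
        v[50] = 20.0
        fixed, mask = despike_moving_sd(make_channel("HbO2", v))
        assert mask.flags[50]
        assert mask.flags.sum() == 1
        assert fixed.values[50] == pytest.approx(10.0, abs=1e-6)

    def test_constant_channel_nothing_flagged(self):
        _, mask = despike_moving_sd(make_channel("HbO2", np.full(100, 3.0)))
        assert not mask.flags.any()

    def test_pure_sinusoid_low_false_positive_rate(self):
        t = np.arange(2000.0)
        v = np.sin(2 * np.pi * 0.01 * t)
        _, mask = despike_moving_sd(make_channel("HbO2", v), 20, 3.0)
        assert mask.flags.mean() < 0.01

    def test_spike_train_positions_recovered(self, rng):
        t = np.arange(1000.0)
        v = np.sin(2 * np.pi * 0.005 * t) + 0.02 * rng.standard_normal(1000)
        truth = np.array([100, 300, 550, 800])
        v[truth] += 3.0
        _, mask = despike_moving_sd(make_channel("HbO2", v), 20, 3.0)
        found = np.flatnonzero(mask.flags)
        for pos in truth:
            assert np.min(np.abs(found - pos)) <= 1

    def test_window_below_five_samples_errors(self):
        with pytest.raises(DataError):
            despike_moving_sd(make_channel("HbO2", np.ones(50)), window=3)


class TestWaveletDenoise:
    def test_noiseless_slow_sinusoid_preserved(self):
        t = np.arange(4096.0)
        v = np.sin(2 * np.pi * 0.01 * t)
        out = wavelet_denoise(make_channel("oxCCO", v))
        r = np.corrcoef(out.values, v)[0, 1]
        assert r >= 0.999
        assert len(out) == len(v)

    def test_denoising_reduces_rmse_at_0db(self):
        # SNR 0 dB: noise SD equals signal SD; 100-seed Monte-Carlo
        t = np.arange(2048.0)
        clean = np.sin(2 * np.pi * 0.01 * t)
        sd = clean.std()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + sd * rng.standard_normal(t.size)
            out = wavelet_denoise(make_channel("oxCCO", noisy))
            rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
            rmse_after = np.sqrt(np.mean((out.values - clean) ** 2))
            assert rmse_after < rmse_before

    def test_band_power_change_below_5pct(self, rng):
        from slowwave.simulate import band_limited_noise
        v = band_limited_noise(4096, 1.0, (0.003, 0.05), rng)
        out = wavelet_denoise(make_channel("oxCCO", v))
        f, p_in = periodogram(v, fs=1.0)
        _, p_out = periodogram(out.values, fs=1.0)
        band = (f >= 0.003) & (f <= 0.05)
        assert abs(p_out[band].sum() / p_in[band].sum() - 1.0) <= 0.05

    def test_too_short_input_errors(self):
        with pytest.raises(DataError):
            wavelet_denoise(make_channel("oxCCO", np.ones(8)))


class TestSynchronize:
    def test_mixed_rates_onto_shared_base(self, rng):
        fast = make_channel("MABP", 50 + rng.standard_normal(1000), rate=10.0)
        slow = make_channel("BFI", 1 + 0.01 * rng.standard_normal(100), rate=1.0)
        rec = make_recording([fast, slow])
        out = synchronize(rec, 1.0)
        a, b = out.channels["MABP"], out.channels["BFI"]
        assert len(a) == len(b)
        np.testing.assert_array_equal(a.times, b.times)
        assert a.native_rate == 1.0

    def test_sinusoid_amplitude_preserved_through_decimation(self):
        t = np.arange(0, 2000, 0.1)
        v = np.sin(2 * np.pi * 0.01 * t)
        rec = make_recording([make_channel("MABP", 50 + v, rate=10.0)])
        out = synchronize(rec, 1.0)
        got = out.channels["MABP"].values
        # compare steady-state amplitude, skipping filter edges
        amp = 0.5 * (got[200:-200].max() - got[200:-200].min())
        assert abs(amp - 1.0) <= 0.01

    def test_already_synchronized_identity(self, rng):
        v = 50 + rng.standard_normal(500)
        rec = make_recording([make_channel("MABP", v, rate=1.0),
                              make_channel("BFI", v * 1e-8, rate=1.0)])
        out = synchronize(rec, 1.0)
        np.testing.assert_allclose(out.channels["MABP"].values, v, atol=1e-9)

    def test_upsampling_warns(self, rng):
        rec = make_recording([make_channel("HbO2", rng.standard_normal(50), rate=0.5)])
        with pytest.warns(UserWarning, match="upsampling"):
            synchronize(rec, 1.0)

    def test_disjoint_channels_error(self):
        a = make_channel("MABP", np.ones(10), t0=0.0)
        b = make_channel("BFI", np.ones(10), t0=100.0)
        with pytest.raises(DataError, match="overlap"):
            synchronize(make_recording([a, b]), 1.0)


class TestDeriveChannels:
    def test_sum_and_difference(self):
        rec = make_recording([make_channel("HbO2", np.full(10, 2.0)),
                              make_channel("HHb", np.full(10, 1.0))])
        out = derive_channels(rec)
        assert np.all(out.channels["HbD"].values == 1.0)
        assert np.all(out.channels["HbT"].values == 3.0)

    def test_equal_inputs_zero_difference(self, rng):
        v = rng.standard_normal(20)
        rec = make_recording([make_channel("HbO2", v), make_channel("HHb", v.copy())])
        out = derive_channels(rec)
        assert np.all(out.channels["HbD"].values == 0.0)

    def test_existing_derived_channels_pass_through(self, rng):
        hbd = make_channel("HbD", rng.standard_normal(20))
        hbt = make_channel("HbT", rng.standard_normal(20))
        rec = make_recording([hbd, hbt])
        out = derive_channels(rec)
        np.testing.assert_array_equal(out.channels["HbD"].values, hbd.values)

    def test_missing_constituents_error(self):
        rec = make_recording([make_channel("MABP", np.ones(10))])
        with pytest.raises(DataError, match="HbO2"):
            derive_channels(rec)


class TestChain:
    def test_chain_idempotent_within_tolerance(self):
        from slowwave.simulate import SubjectGenSpec, generate_subject
        spec = SubjectGenSpec(duration_s=2400.0)
        rec, _ = generate_subject(spec, 42)
        cfg = AnalysisConfig(epoch=EpochSpec(0, 1800))
        once = preprocess_recording(rec, cfg)
        twice = preprocess_recording(once, cfg)
        for nm in ("HbD", "HbT", "BFI", "MABP"):
            a, b = once.channels[nm].values, twice.channels[nm].values
            assert len(a) == len(b)
            scale = np.max(np.abs(a)) or 1.0
            assert np.max(np.abs(a - b)) / scale <= 1e-6

    def test_chain_preserves_shared_length(self):
        from slowwave.simulate import SubjectGenSpec, generate_subject
        spec = SubjectGenSpec(duration_s=2400.0,
                              rates_hz={"MABP": 5.0, "HbO2": 1.0, "HHb": 1.0,
                                        "oxCCO": 1.0, "BFI": 1.0})
        rec, _ = generate_subject(spec, 7)
        out = preprocess_recording(rec, AnalysisConfig())
        lengths = {len(ch) for ch in out.channels.values()}
        assert len(lengths) == 1
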