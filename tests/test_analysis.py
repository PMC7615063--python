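import numpy as np
import pytest
from scipy import stats

from riftbci.analysis import (
    Epochs,
    GAME_WINDOW,
    TRAINING_WINDOW,
    cluster_permutation,
    epoch,
    eye_power_histogram,
    gaze_containment,
    itr,
    preprocess,
    sliding_power,
    snr,
    tfr_hanning,
)
from riftbci.decode import psd_at
from riftbci.synthmeg import Recording

SR = 1000.0


def sine_recording(freq, duration=10.0, amp=1.0):
    t = np.arange(int(duration * SR)) / SR
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(x[None, :], SR, ["m0"], ["meg"])


class TestPreprocess:
    def test_notch_attenuates_50hz_by_20db(self):
        rec = preprocess(sine_recording(50.0))
        rms_in = 1.0 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(rec.data[0, 2000:-2000] ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 20

    def test_highpass_removes_slow_drift(self):
        rec = preprocess(sine_recording(0.2, duration=30.0))
        rms_out = np.sqrt(np.mean(rec.data[0, 5000:-5000] ** 2))
        assert rms_out < 0.1 / np.sqrt(2)

    def test_56hz_passes_nearly_unchanged(self):
        rec = preprocess(sine_recording(56.0))
        amp_out = np.sqrt(2 * np.mean(rec.data[0, 2000:-2000] ** 2))
        assert abs(amp_out - 1.0) < 0.05

    def test_gaze_channels_untouched(self, training1):
        rec, _ = training1
        out = preprocess(rec)
        assert np.array_equal(out.gaze_x(), rec.gaze_x(), equal_nan=True)

    def test_rejects_low_sampling_rate(self):
        rec = Recording(np.zeros((1, 1000)), 150.0, ["m"], ["meg"])
        with pytest.raises(ValueError):
            preprocess(rec)


class TestEpoch:
    def test_training_session_gives_80_four_second_epochs(self, training1):
        rec, labels = training1
        ep = epoch(rec, (11, 12), TRAINING_WINDOW, {11: "left", 12: "right"})
        assert ep.n_trials == 80
        assert ep.data.shape[1:] == (7, 4000)
        assert ep.times[0] == pytest.approx(-1.0)
        assert ep.labels == list(labels)

    def test_out_of_bounds_trials_dropped_and_counted(self):
        rec = Recording(
            np.zeros((1, 5000)), SR, ["m"], ["meg"], events=[(100, 30), (4000, 30)]
        )
        ep = epoch(rec, 30, GAME_WINDOW)
        assert ep.n_trials == 1
        assert ep.n_dropped == 1

    def test_no_matching_events_gives_empty_epochs(self):
        rec = Recording(np.zeros((1, 5000)), SR, ["m"], ["meg"])
        ep = epoch(rec, 30, (-1.0, 1.0))
        assert ep.n_trials == 0


def burst_epochs(freq=56.0, n_trials=8, seed=0):
    """Epochs [-1, 3] s with a 2-s sinusoidal burst in [0, 2] s plus noise."""
    rng = np.random.default_rng(seed)
    times = np.arange(4000) / SR - 1.0
    data = 0.1 * rng.standard_normal((n_trials, 2, 4000))
    burst = (times >= 0) & (times < 2)
    data[:, :, burst] += np.sin(2 * np.pi * freq * times[burst])
    return Epochs(data=data, times=times, labels=["x"] * n_trials, srate=SR)


class TestTFR:
    def test_burst_power_rises_then_returns_to_baseline(self):
        tfr = tfr_hanning(burst_epochs())
        fi = np.argmin(np.abs(tfr.freqs - 56.0))
        during = (tfr.times > 0.3) & (tfr.times < 1.7)
        after = tfr.times > 2.4
        p = tfr.power[0, fi]
        assert np.nanmean(p[during]) > 10 * np.nanmean(p[after])

    def test_white_noise_has_no_systematic_peak(self):
        rng = np.random.default_rng(3)
        ep = Epochs(
            data=rng.standard_normal((20, 2, 2000)),
            times=np.arange(2000) / SR - 0.5,
            labels=["x"] * 20,
            srate=SR,
        )
        tfr = tfr_hanning(ep)
        avail = tfr.available.all(axis=0)
        p = tfr.power[:, :, avail]
        assert np.nanmax(p) / np.nanmedian(p) < 3.5  # bound set by simulation

    @pytest.mark.parametrize("freq", [41.5, 50.0, 56.0, 63.3, 69.0])
    def test_pure_sinusoid_peaks_at_nearest_bin(self, freq):
        t = np.arange(3000) / SR - 0.5
        data = np.sin(2 * np.pi * freq * t)[None, None, :].repeat(2, axis=0)
        ep = Epochs(data=data, times=t, labels=["x", "x"], srate=SR)
        tfr = tfr_hanning(ep)
        mid = np.argmin(np.abs(tfr.times - 1.0))
        peak = tfr.freqs[np.nanargmax(tfr.power[0, :, mid])]
        assert abs(peak - freq) <= 0.5 + 1e-9

    def test_edges_marked_unavailable_not_zero(self):
        tfr = tfr_hanning(burst_epochs())
        fi = 0  # 40 Hz: longest window, widest unavailable margin
        assert np.isnan(tfr.power[0, fi, 0])
        assert not tfr.available[fi, 0]

    def test_rejects_too_short_epochs(self):
        ep = Epochs(
            data=np.zeros((2, 1, 300)),
            times=np.arange(300) / SR,
            labels=["x", "x"],
            srate=SR,
        )
        with pytest.raises(ValueError):
            tfr_hanning(ep)


class TestSnr:
    def test_arithmetic(self):
        freqs = [54.0, 56.0, 58.0]
        assert snr(freqs, [2.0, 4.0, 2.0], 56.0) == pytest.approx(2.0)

    def test_flat_spectrum_is_one(self):
        freqs = np.arange(40.0, 70.0)
        assert snr(freqs, np.ones(30), 56.0) == pytest.approx(1.0)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            snr([54.0, 56.0, 58.0], [0.0, 1.0, 0.0], 56.0)

    def test_missing_frequency_is_an_error(self):
        with pytest.raises(ValueError):
            snr([56.0, 58.0], [1.0, 1.0], 56.0)


class TestItr:
    def test_chance_gives_zero_bits(self):
        assert itr(2, 0.5, 10, 5.0) == pytest.approx(0.0)

    def test_perfect_two_trials_per_minute(self):
        assert itr(2, 1.0, 10, 5.0) == pytest.approx(2.0)

    def test_known_value_at_75_percent(self):
        # independent closed-form evaluation:
        # bits = 1 + 0.75*log2(0.75) + 0.25*log2(0.25/1) = 0.18872...
        expected = (1 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)) * 20 / 5
        assert itr(2, 0.75, 20, 5.0) == pytest.approx(expected)
        assert itr(2, 0.75, 20, 5.0) == pytest.approx(0.755, abs=1e-3)

    def test_monotone_in_accuracy_and_linear_in_rate(self):
        ps = np.linspace(0.5, 1.0, 21)
        vals = [itr(2, p, 10, 5.0) for p in ps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert itr(2, 0.8, 20, 5.0) == pytest.approx(2 * itr(2, 0.8, 10, 5.0))

    def test_rejects_below_chance(self):
        with pytest.raises(ValueError):
            itr(2, 0.4, 10, 5.0)

    def test_printed_variant_negative_at_chance(self):
        assert itr(2, 0.5, 10, 5.0, printed_formula=True) < 0


class TestSlidingPower:
    def test_stationary_sinusoid_gives_flat_trace(self):
        t = np.arange(10_000) / SR
        x = np.sin(2 * np.pi * 56 * t)
        _, p = sliding_power(x, 56.0)
        assert np.std(p) / np.mean(p) < 0.01

    def test_step_increase_ramps_within_one_second(self):
        t = np.arange(10_000) / SR
        amp = np.where(t < 5.0, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 56 * t)
        times, p = sliding_power(x, 56.0)
        assert np.allclose(p[times < 5.0], p[0], rtol=1e-6)
        after = p[times > 6.05]
        assert np.allclose(after, after[0], rtol=1e-6)
        assert after[0] == pytest.approx(4 * p[0], rel=1e-6)

    def test_matches_naive_recompute_at_random_points(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8000)
        times, p = sliding_power(x, 60.0)
        for i in rng.choice(p.size, 100, replace=False):
            end = int(round(times[i] * SR))
            assert p[i] == pytest.approx(psd_at(x[end - 1000 : end], 60.0, SR), rel=1e-9)

    def test_final_window_equals_online_psd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        _, p = sliding_power(x, 56.0)
        assert p[-1] == pytest.approx(psd_at(x[-1000:], 56.0, SR), rel=1e-9)

    def test_rejects_non_bin_aligned_frequency(self):
        with pytest.raises(ValueError):
            sliding_power(np.zeros(2000), 56.5)


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 50))
        res = cluster_permutation(a, a.copy(), n_perm=200, seed=0)
        assert res.clusters == []

    def test_large_shift_gives_one_full_length_cluster(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 40))
        b = a + 5.0 + 0.1 * rng.standard_normal((10, 40))
        res = cluster_permutation(b, a, n_perm=500, seed=0)
        sig = res.significant_clusters
        assert len(sig) == 1
        assert (sig[0].start, sig[0].end) == (0, 40)
        assert sig[0].p == pytest.approx(1 / 501)  # minimal attainable

    def test_monte_carlo_matches_exhaustive_at_n5(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((5, 30))
        b = a + 1.2 + 0.8 * rng.standard_normal((5, 30))
        exact = cluster_permutation(b, a, exhaustive=True)
        mc = cluster_permutation(b, a, n_perm=4000, seed=1)
        assert len(exact.clusters) == len(mc.clusters) > 0
        for ce, cm in zip(exact.clusters, mc.clusters):
            assert (ce.start, ce.end) == (cm.start, cm.end)
            assert cm.p == pytest.approx(ce.p, abs=0.05)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 10)), np.zeros((4, 9)))
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 10)), np.zeros((1, 10)))


class TestEyeAnalyses:
    def test_all_gaze_at_zero_occupies_one_bin(self):
        power = np.abs(np.random.default_rng(0).standard_normal(500)) + 1
        centers, mean_p, counts = eye_power_histogram(np.zeros(500), power)
        assert (counts > 0).sum() == 1
        occupied = np.flatnonzero(counts)[0]
        assert mean_p[occupied] == pytest.approx(power.mean())

    def test_uniform_gaze_occupies_all_40_bins(self):
        rng = np.random.default_rng(1)
        gaze = rng.uniform(-2, 2, 20_000)
        power = np.ones(20_000)
        _, mean_p, counts = eye_power_histogram(gaze, power)
        assert (counts > 0).all()
        assert np.allclose(mean_p, 1.0)

    def test_independent_gaze_and_power_show_no_rank_trend(self):
        rng = np.random.default_rng(2)
        gaze = rng.normal(0, 0.5, 50_000)
        power = np.abs(rng.standard_normal(50_000))
        centers, mean_p, counts = eye_power_histogram(gaze, power)
        ok = counts > 10
        rho, p = stats.spearmanr(centers[ok], mean_p[ok])
        assert p > 0.05

    def test_containment_of_zero_gaze_is_total(self):
        frac = gaze_containment(np.zeros(100))
        assert frac[1.0] == 1.0 and frac[2.0] == 1.0

    def test_blink_gaps_excluded(self):
        g = np.array([0.0, np.nan, 3.0, 0.5])
        frac = gaze_containment(g)
        assert frac[1.0] == pytest.approx(2 / 3)
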