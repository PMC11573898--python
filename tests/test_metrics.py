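"""Spectral summaries, filtering, SWR detection, couplings, F1/permutation,
imputation correlation, and the memorization check."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from neurodiff import metrics as M
from neurodiff.synthetic import ar1_spectrum, gen_ar1_windows, gen_pac_recording


class TestPSD:
    def test_sine_peak_at_frequency(self):
        fs, L, f0 = 200.0, 512, 25.0
        t = np.arange(L) / fs
        freqs, pxx = M.compute_psd(np.sin(2 * np.pi * f0 * t), fs)
        assert freqs[np.argmax(pxx)] == pytest.approx(f0, abs=fs / L)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        freqs, pxx = M.compute_psd(x, 1.0)
        # one-sided periodogram integrates to the signal power
        df = freqs[1] - freqs[0]
        assert np.sum(pxx) * df == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_white_noise_flat_median(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((3000, 128))
        s = M.psd_percentiles(w, 2.0)
        inner = s.median[1:-1]
        assert np.abs(inner / inner.mean() - 1.0).max() < 0.15

    def test_identical_windows_degenerate_percentiles(self):
        w = np.tile(np.sin(np.arange(64.0)), (5, 1))
        s = M.psd_percentiles(w, 10.0)
        assert np.allclose(s.median, s.p10)
        assert np.allclose(s.median, s.p90)

    def test_percentile_ordering_invariant(self):
        rng = np.random.default_rng(2)
        s = M.psd_percentiles(rng.standard_normal((50, 64)), 1.0)
        assert np.all(s.p10 <= s.median + 1e-15)
        assert np.all(s.median <= s.p90 + 1e-15)

    def test_ar1_median_matches_lorentzian(self):
        # OU/AR(1) ensemble median tracks ln2 x analytic spectrum
        ws, _ = gen_ar1_windows(n=3000, length=128, fs=200.0, phi=0.9, seed=3)
        s = M.psd_percentiles(ws.windows[:, 0, :], 200.0)
        band = (s.freqs >= 5) & (s.freqs <= 80)
        ana = np.log(2.0) * ar1_spectrum(s.freqs[band], 0.9, 200.0)
        dev_db = 10 * np.log10(s.median[band] / ana)
        assert np.abs(dev_db).max() < 1.0

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            M.compute_psd(np.array([1.0]), 1.0)


class TestTrialAverage:
    def test_identical_trials_zero_sd(self):
        tr = np.tile(np.arange(12.0), (4, 1, 1))
        mean, sd = M.trial_average(tr)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, tr[0])

    def test_mean_of_opposites_is_zero(self):
        x = np.random.default_rng(0).standard_normal((1, 16))
        mean, _ = M.trial_average(np.stack([x, -x]))
        assert np.allclose(mean, 0.0)

    def test_erp_recovery_improves_with_n(self):
        from neurodiff.synthetic import gen_evoked_trials

        errs = []
        for n in (25, 400):
            ws, meta = gen_evoked_trials(n=n, length=128, fs=200.0, seed=5)
            mean, _ = M.trial_average(ws.windows)
            errs.append(np.sqrt(np.mean((mean[0] - meta["template"][:128]) ** 2)))
        # RMSE ~ 1/sqrt(n): 16x more trials -> ~4x smaller error
        assert errs[1] < errs[0] / 2.5

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            M.trial_average(np.zeros((1, 2, 8)))


class TestBandpass:
    @pytest.mark.parametrize("method", ["fir_hamming", "butterworth"])
    def test_in_band_gain_near_unity(self, method):
        fs, L = 600.0, 3000
        t = np.arange(L) / fs
        x = np.sin(2 * np.pi * 150.0 * t)
        y = M.bandpass(x, fs, 100.0, 275.0, method=method)
        mid = slice(L // 4, 3 * L // 4)
        gain = y[mid].std() / x[mid].std()
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self):
        x = np.ones(2000) * 5.0
        y = M.bandpass(x, 600.0, 100.0, 275.0)
        # > 40 dB attenuation of a constant offset
        assert abs(y[500:-500].mean()) < 5.0 * 1e-2

    @pytest.mark.parametrize("method", ["fir_hamming", "butterworth"])
    def test_out_of_band_attenuation(self, method):
        fs, L = 600.0, 3000
        t = np.arange(L) / fs
        x = np.sin(2 * np.pi * 20.0 * t)
        y = M.bandpass(x, fs, 100.0, 275.0, method=method)
        mid = slice(L // 4, 3 * L // 4)
        att_db = 20 * np.log10(x[mid].std() / (y[mid].std() + 1e-300))
        assert att_db > 20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            M.bandpass(np.zeros(100), 600.0, 275.0, 100.0)


def _burst_signal(fs=600.0, L=1200, bursts=(), amp=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(L) / fs
    x = noise * rng.standard_normal(L)
    for start, length in bursts:
        tb = np.arange(length) / fs
        x[start : start + length] += amp * np.hanning(length) * np.sin(
            2 * np.pi * 150.0 * tb
        )
    return x


@pytest.fixture(scope="module")
def background_stats():
    """Reference ripple-power stats from a clean (burst-free) noise ensemble."""
    rng = np.random.default_rng(9)
    bg = 0.2 * rng.standard_normal((40, 1200))
    return M.ripple_power_stats(bg, 600.0)


class TestSWRDetection:
    def test_flat_zero_no_events(self, background_stats):
        assert M.detect_swr(np.zeros(1200), 600.0, background_stats) == []

    def test_single_burst_detected_once(self, background_stats):
        x = _burst_signal(bursts=[(500, 40)], amp=2.0)
        events = M.detect_swr(x, 600.0, background_stats)
        assert len(events) == 1
        ev = events[0]
        assert ev.start <= 500 + 20 <= ev.end
        assert ev.start <= ev.peak < ev.end

    def test_nearby_bursts_fused(self, background_stats):
        # two supra-threshold runs separated by < 10 samples -> one event
        t = np.arange(1200) / 600.0
        carrier = np.sin(2 * np.pi * 150.0 * t)
        x = np.zeros(1200)
        x[400:425] = 2.0 * carrier[400:425]
        x[430:455] = 2.0 * carrier[430:455]
        events = M.detect_swr(x, 600.0, background_stats)
        assert len(events) == 1
        assert events[0].end - events[0].start >= 40

    def test_short_burst_discarded(self, background_stats):
        # an isolated supra-threshold blip shorter than 20 samples
        t = np.arange(1200) / 600.0
        x = np.zeros(1200)
        x[600:615] = 3.0 * np.sin(2 * np.pi * 150.0 * t[600:615])
        events = M.detect_swr(x, 600.0, background_stats, fuse_gap=1)
        assert events == []

    def test_recall_and_false_alarms_on_synthetic(self, background_stats):
        # >= 90% of injected ripples recovered, none invented on clean noise
        rng = np.random.default_rng(11)
        hits, total, false_events = 0, 0, 0
        for i in range(30):
            starts = rng.choice(np.arange(100, 1000, 120), size=3, replace=False)
            x = _burst_signal(bursts=[(s, 40) for s in starts], amp=2.0,
                              noise=0.2, seed=100 + i)
            events = M.detect_swr(x, 600.0, background_stats)
            total += 3
            for s in starts:
                if any(ev.start <= s + 20 < ev.end for ev in events):
                    hits += 1
            clean = 0.2 * np.random.default_rng(200 + i).standard_normal(1200)
            false_events += len(M.detect_swr(clean, 600.0, background_stats))
        assert hits / total >= 0.9
        assert false_events == 0

    def test_low_fs_rejected(self, background_stats):
        with pytest.raises(ValueError):
            M.detect_swr(np.zeros(100), 500.0, background_stats)


class TestCoupling:
    def test_pac_profile_shape_and_flatness_without_coupling(self):
        rng = np.random.default_rng(3)
        fs, L = 600.0, 60000
        phase_src = np.sin(2 * np.pi * 4.0 * np.arange(L) / fs)
        amp_src = rng.standard_normal(L)
        prof = M.phase_amplitude_coupling(phase_src, amp_src, fs, (1.0, 8.0))
        assert len(prof.values) == 31
        assert np.nanmax(prof.values) / np.nanmin(prof.values) < 1.2

    def test_pac_peak_at_locked_phase(self):
        ws, meta = gen_pac_recording(
            n=40, coupling=1.0, locked_phase_deg=0.0, burst_rate=2.0, seed=7
        )
        vals = np.zeros(31)
        for w in ws.windows:
            prof = M.phase_amplitude_coupling(w[0], w[1], ws.fs, (2.0, 8.0))
            vals += np.nan_to_num(prof.values)
        peak = prof.bin_centers[np.argmax(vals)]
        bin_w = 360.0 / 31
        assert abs(peak) <= 1.5 * bin_w  # injected phase +- one bin

    def test_pac_invariant_to_phase_channel_scale(self):
        ws, _ = gen_pac_recording(n=4, seed=8)
        w = ws.windows[0]
        a = M.phase_amplitude_coupling(w[0], w[1], ws.fs, (2.0, 8.0))
        b = M.phase_amplitude_coupling(10.0 * w[0], w[1], ws.fs, (2.0, 8.0))
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_phase_count_conservation_and_peak(self):
        # reference power stats from burst-free background of the same law,
        # so the threshold reflects the background and not the injections
        bg, _ = gen_pac_recording(n=40, burst_amp=0.0, seed=100)
        stats = M.ripple_power_stats(bg.windows[:, 1, :], bg.fs)
        ws, meta = gen_pac_recording(
            n=100, coupling=1.0, locked_phase_deg=90.0, burst_rate=1.0, seed=9
        )
        counts = np.zeros(21)
        n_events = 0
        for w in ws.windows:
            events = M.detect_swr(w[1], ws.fs, stats)
            prof = M.phase_count_coupling(events, w[0], ws.fs, (2.0, 8.0))
            assert len(prof.values) == 21
            assert prof.values.sum() == len(events)
            counts += prof.values
            n_events += len(events)
        assert n_events > 100
        peak = prof.bin_centers[np.argmax(counts)]
        bin_w = 360.0 / 21
        # 90 deg lies in the bin centered at 85.7; allow the adjacent bin too
        assert abs(peak - 90.0) <= 1.5 * bin_w

    def test_empty_event_list_gives_zero_histogram(self):
        prof = M.phase_count_coupling([], np.sin(np.arange(1200) / 10), 600.0, (1.0, 8.0))
        assert prof.values.sum() == 0


class TestF1:
    def test_perfect_agreement(self):
        assert M.f1_swr_prediction([1, 0, 1], [1, 0, 1]) == 1.0

    def test_formula_example(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1)
        real = [1, 1, 1, 0, 0]
        pred = [1, 1, 0, 1, 0]
        assert M.f1_swr_prediction(real, pred) == pytest.approx(2 / 3)

    def test_all_negative_predictions(self):
        assert M.f1_swr_prediction([1, 0, 1], [0, 0, 0]) == 0.0

    def test_matches_exhaustive_confusion_matrix(self):
        # every (real, pred) pair up to length 6
        for n in range(1, 7):
            for real in itertools.product([0, 1], repeat=n):
                for pred in itertools.product([0, 1], repeat=n):
                    tp = sum(r and p for r, p in zip(real, pred))
                    fp = sum((not r) and p for r, p in zip(real, pred))
                    fn = sum(r and (not p) for r, p in zip(real, pred))
                    expect = 1.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
                    assert M.f1_swr_prediction(real, pred) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.f1_swr_prediction([], [])


class TestPermutationTest:
    def test_constant_predictions_p_one(self):
        assert M.permutation_test([1, 0, 1, 0], [1, 1, 1, 1], n_perm=50) == 1.0

    def test_perfect_predictions_minimal_p(self):
        rng = np.random.default_rng(0)
        real = rng.uniform(size=200) < 0.5
        p = M.permutation_test(real, real, n_perm=99, rng=1)
        assert p == pytest.approx(1 / 100)

    def test_null_p_values_uniform(self):
        # simulated null: independent flags; KS must not reject at alpha=0.01
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(500):
            n = int(rng.integers(2000, 4000))
            real = rng.uniform(size=n) < rng.uniform(0.2, 0.8)
            pred = rng.uniform(size=n) < rng.uniform(0.2, 0.8)
            pvals.append(M.permutation_test(real, pred, n_perm=199, rng=rng))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestImputationCorrelation:
    def test_identity_imputation(self):
        x = np.random.default_rng(0).standard_normal((3, 2, 32))
        assert M.channelwise_correlation(x, x, np.array([False, True])) == 1.0

    def test_orthogonal_signals_zero(self):
        t = np.arange(256) / 256
        truth = np.sin(2 * np.pi * 8 * t)[None, None, :]
        imput = np.cos(2 * np.pi * 8 * t)[None, None, :]
        c = M.channelwise_correlation(truth, imput, np.array([True]))
        assert abs(c) < 1e-10

    def test_constant_channel_excluded_with_warning(self):
        truth = np.random.default_rng(1).standard_normal((1, 2, 16))
        imput = truth.copy()
        imput[0, 0] = 0.0  # mean imputation -> constant -> undefined correlation
        with pytest.warns(UserWarning):
            c = M.channelwise_correlation(truth, imput, np.array([True, True]))
        assert c == pytest.approx(1.0)


class TestMemorization:
    def test_copies_flagged_as_zero_distance(self):
        tr = np.random.default_rng(0).standard_normal((20, 1, 32))
        res = M.memorization_check(tr, tr[:5].copy())
        assert np.allclose(res["generated_min"], 0.0)

    def test_fresh_draws_match_train_distribution(self):
        rng = np.random.default_rng(1)
        tr = rng.standard_normal((150, 1, 32))
        ge = rng.standard_normal((150, 1, 32))
        res = M.memorization_check(tr, ge)
        assert res["ks_pvalue"] > 0.01

    def test_nonnegative_and_frequency_consistency(self):
        rng = np.random.default_rng(2)
        tr = rng.standard_normal((10, 1, 16))
        ge = np.concatenate([tr[:2].copy(), rng.standard_normal((3, 1, 16))])
        t_res = M.memorization_check(tr, ge, domain="time")
        f_res = M.memorization_check(tr, ge, domain="frequency")
        assert np.all(t_res["generated_min"] >= 0)
        # exact time-domain copies are exact frequency-domain copies
        assert np.allclose(f_res["generated_min"][:2], 0.0, atol=1e-6)
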