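"""Phase-locking metrics: VS, Rayleigh z, ISI spectra, z-ratios, tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import tfs1kit as tk
from tfs1kit import spikes as sp, metrics as mt


def comb_trains(freq_hz, n_reps=5, jitter=0.0, seed=0):
    """Perfectly (or jittered) periodic trains in the standard window."""
    rng = np.random.default_rng(seed)
    base = np.arange(0.0125, 0.3875, 1.0 / freq_hz)
    reps = []
    for _ in range(n_reps):
        t = base + jitter * rng.standard_normal(len(base))
        reps.append(np.sort(np.clip(t, 0.0125, 0.38749)))
    return sp.SpikeTrainSet(reps)


class TestVsAt:
    def test_perfect_locking(self):
        trains = comb_trains(400.0)
        v, n, z = mt.vs_at(trains, 400.0)
        assert v == pytest.approx(1.0, abs=1e-12)
        assert z == pytest.approx(n)

    def test_stated_arithmetic(self):
        # z = N_avg * V_avg^2 regardless of how the inputs arose
        trains = comb_trains(400.0, n_reps=1)
        v, n, z = mt.vs_at(trains, 400.0)
        assert z == n * v ** 2

    def test_double_loop_oracle_equivalence(self):
        """vs_at matches the naive two-loop evaluation of |sum exp|^2 to
        1e-12 on trains of <= 200 spikes."""
        rng = np.random.default_rng(3)
        for f in (213.7, 800.0, 1951.3):
            t1 = np.sort(rng.uniform(0.0125, 0.3875, 150))
            v, _, _ = mt.vs_at(sp.SpikeTrainSet([t1]), f)
            acc = 0.0
            for a in t1:
                for b in t1:
                    acc += np.cos(2 * np.pi * f * (a - b))
            assert abs(v - np.sqrt(acc) / len(t1)) < 1e-12

    def test_time_shift_invariance(self):
        trains = comb_trains(400.0, jitter=2e-4, seed=1)
        shifted = sp.SpikeTrainSet(
            [t + 0.01 for t in trains.spike_times_s],
            analysis_window_s=(0.0225, 0.3975))
        v0 = mt.vs_at(trains, 400.0)[0]
        v1 = mt.vs_at(shifted, 400.0)[0]
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_zero_spike_reps_excluded_from_v_counted_in_n(self):
        trains = sp.SpikeTrainSet([np.arange(0.0125, 0.3875, 0.0025),
                                   np.array([])])
        v, n, z = mt.vs_at(trains, 400.0)
        assert v == pytest.approx(1.0)
        assert n == pytest.approx(len(trains.spike_times_s[0]) / 2)

    def test_rayleigh_null_mean_near_one(self, uniform_trains):
        """For single unlocked trains z ~ Exp(1): mean near 1, z > 3 rare."""
        zs = [mt.vs_at(uniform_trains(n_reps=1, mean_count=100, seed=s),
                       800.0)[2] for s in range(500)]
        assert np.mean(zs) == pytest.approx(1.0, abs=0.15)
        assert np.mean(np.array(zs) > 3) < 0.08

    @given(f=hs.floats(min_value=50, max_value=5000))
    @settings(max_examples=25, deadline=None)
    def test_vs_bounds(self, f):
        trains = comb_trains(317.0, n_reps=3, jitter=1e-3, seed=2)
        v, n, z = mt.vs_at(trains, f)
        assert 0.0 <= v <= 1.0
        assert z >= 0.0


class TestIsiSpectrum:
    def test_spectral_resolution_1p33_hz(self):
        spec = mt.isi_vs_spectrum(comb_trains(400.0))
        assert spec.resolution_hz == pytest.approx(4.0 / 3.0, abs=1e-9)

    def test_comb_train_peaks_at_frequency_and_harmonics(self):
        spec = mt.isi_vs_spectrum(comb_trains(400.0))
        nonzero = spec.freqs_hz > 10
        top = spec.freqs_hz[nonzero][np.argmax(spec.vs[nonzero])]
        assert top == pytest.approx(400.0, abs=spec.resolution_hz)
        assert spec.at(800.0) > 0.5  # harmonic of the comb

    def test_agrees_with_single_frequency_vs(self, tone_1khz):
        """Spectrum VS at the locked frequency matches the direct VS within
        the documented Gaussian-window bias (0.05)."""
        diffs = []
        for s in range(25):
            fib = tk.FiberModel(sr_sp_s=10, driven_sp_s=150, bf_hz=1000,
                                tfs_gain=0.8, seed=s)
            trains = sp.simulate(fib, tone_1khz, 20, seed=300 + s)
            spec = mt.isi_vs_spectrum(trains)
            diffs.append(spec.at(1000.0) - mt.vs_at(trains, 1000.0)[0])
        assert np.max(np.abs(diffs)) < 0.05

    def test_window_free_limit_closed_form(self):
        """With an infinite window the spectrum VS equals the pooled
        N^2-weighted RMS of single-repetition VS values."""
        trains = comb_trains(400.0, n_reps=5, jitter=3e-4, seed=4)
        spec = mt.isi_vs_spectrum(trains, window_sd_s=np.inf)
        counts = [len(t) for t in trains.windowed()]
        vs_r = [mt.vs_at(sp.SpikeTrainSet([t]), 400.0)[0]
                for t in trains.windowed()]
        closed = np.sqrt(sum(n * n * v * v for n, v in zip(counts, vs_r))
                         / sum(n * n for n in counts))
        assert spec.at(400.0) == pytest.approx(closed, abs=0.02)

    def test_vs_bounded_and_finite(self):
        spec = mt.isi_vs_spectrum(comb_trains(317.0, jitter=1e-3, seed=5))
        assert np.all(np.isfinite(spec.vs))
        assert np.all(spec.vs >= 0)
        assert np.all(spec.vs[spec.freqs_hz > 10] <= 1.0 + 1e-9)

    def test_no_intervals_error(self):
        with pytest.raises(ValueError, match="no intervals"):
            mt.isi_vs_spectrum(sp.SpikeTrainSet([np.array([0.1]),
                                                 np.array([])]))


class TestPsth:
    @pytest.mark.parametrize("f0, width", [(200.0, 0.0005),
                                           (400.0, 0.00025)])
    def test_bin_width_is_tenth_of_period(self, f0, width):
        trains = comb_trains(f0)
        centers, _ = mt.psth(trains, f0)
        assert centers[1] - centers[0] == pytest.approx(width)

    def test_single_spike_rate_normalization(self):
        trains = sp.SpikeTrainSet([np.array([0.10001])]
                                  + [np.array([])] * 39)
        _, rate = mt.psth(trains, 200.0)
        assert rate.max() == pytest.approx(50.0)  # 1/(0.5 ms * 40 reps)

    def test_empty_trains_all_zero(self):
        trains = sp.SpikeTrainSet([np.array([])] * 4)
        _, rate = mt.psth(trains, 200.0)
        assert np.all(rate == 0)


class TestRateHistograms:
    def test_driven_rate_binning(self):
        trains = comb_trains(160.0)  # 60 spikes in 0.375 s -> 160 sp/s
        (centers, rel), _ = mt.rate_histograms([trains], [100.0])
        # driven rate 60 sp/s lands in the [60, 62.5) bin
        assert rel[np.argmin(np.abs(centers - 61.25))] > 0

    def test_normalization(self):
        sets = [comb_trains(f, seed=i)
                for i, f in enumerate((100.0, 150.0, 200.0, 250.0))]
        (c, rel), (cs, rels) = mt.rate_histograms(sets, [10, 20, 30, 40])
        assert abs(rel.sum() - 1.0) < 2.0 / max(len(c), 1)
        assert rels.sum() == pytest.approx(1.0)

    def test_generator_is_shift_blind_in_mean_rate(self, tfs1_400_1600):
        """Mean driven rate does not depend on the component shift (the
        rate-based null result)."""
        w_h, w_i = tfs1_400_1600
        rates_h, rates_i = [], []
        for s in range(12):
            fib = tk.FiberModel(sr_sp_s=10, driven_sp_s=100, bf_hz=1600,
                                tfs_gain=0.5, seed=s)
            rates_h.append(sp.simulate(fib, w_h, 20, seed=s)
                           .mean_rate_sp_s())
            rates_i.append(sp.simulate(fib, w_i, 20, seed=100 + s)
                           .mean_rate_sp_s())
        diff = np.mean(rates_h) - np.mean(rates_i)
        sem = np.std(np.array(rates_h) - np.array(rates_i), ddof=1) \
            / np.sqrt(len(rates_h))
        assert abs(diff) <= 2 * sem + 1e-9


class TestTuning:
    def test_bf_is_argmax(self):
        res = mt.tuning_metrics({1000: 50, 2000: 120, 4000: 60},
                                {20: 5, 30: 40}, [1, 2, 3])
        assert res.bf_hz == 2000

    def test_two_criterion_threshold(self):
        # SR mean 10, SD 5 -> criterion max(16, 15) = 16; 17 > 16 at 25 dB
        sr = [10 - 5, 10, 10 + 5]  # mean 10, sd 5
        res = mt.tuning_metrics({1000: 10, 2000: 40, 4000: 10},
                                {20: 12, 25: 17, 30: 40}, sr)
        assert res.sr_sp_s == pytest.approx(10)
        assert res.sr_sd_sp_s == pytest.approx(5)
        assert res.threshold_db_spl == 25

    def test_threshold_not_reached_flag(self):
        res = mt.tuning_metrics({1000: 10, 2000: 12, 4000: 10},
                                {20: 5, 30: 8}, [10, 10, 10])
        assert res.threshold_db_spl is None
        assert res.threshold_flag == "not reached"

    def test_triangular_halfmax_bandwidth(self):
        freqs = np.linspace(1000, 3000, 21)
        rates = 100 - np.abs(freqs - 2000) / 10.0  # triangle peak 100
        res = mt.tuning_metrics(dict(zip(freqs, rates)),
                                {20: 5, 30: 120}, [0.0, 0.0])
        assert res.halfmax_bandwidth_hz == pytest.approx(1000.0, rel=1e-6)

    def test_one_sided_bandwidth_flag(self):
        res = mt.tuning_metrics({1000: 100, 2000: 80, 4000: 60},
                                {20: 5, 30: 120}, [0.0, 0.0])
        assert res.halfmax_bandwidth_hz is None
        assert res.bandwidth_flag is not None


class TestZMetrics:
    def test_identity_at_zero_shift(self):
        trains = comb_trains(1600.0, jitter=1e-4, seed=6)
        cond = tk.StimulusCondition(f0=400, fc=1600)
        zm = mt.z_metrics(trains, trains, cond, 0.0, 1600.0)
        assert zm.tfs_log_z_ratio == pytest.approx(0.0, abs=1e-12)

    def test_sign_recovers_dominant_gain(self, tfs1_400_1600):
        """Envelope-locked fibers give positive ENV/TFS log-z-ratios and
        fine-structure-locked fibers negative ones, in >=95% of runs."""
        _, w_i = tfs1_400_1600
        cond = w_i.condition
        n_env = n_tfs = 0
        runs = 100
        for s in range(runs):
            fe = tk.FiberModel(sr_sp_s=10, driven_sp_s=150, bf_hz=1600,
                               env_gain=0.9, seed=s)
            te = sp.simulate(fe, w_i, 40, seed=1000 + s)
            zm = mt.z_metrics(te, te, cond, 8.0, 1600.0,
                              sr_sp_s=fe.sr_sp_s, bf_hz=fe.bf_hz)
            n_env += zm.env_tfs_log_z_ratio is not None \
                and zm.env_tfs_log_z_ratio > 0
            ft = tk.FiberModel(sr_sp_s=10, driven_sp_s=150, bf_hz=1600,
                               tfs_gain=0.9, seed=s)
            tt = sp.simulate(ft, w_i, 40, seed=2000 + s)
            zm = mt.z_metrics(tt, tt, cond, 8.0, 1600.0)
            n_tfs += zm.env_tfs_log_z_ratio is not None \
                and zm.env_tfs_log_z_ratio < 0
        assert n_env >= 0.95 * runs
        assert n_tfs >= 0.95 * runs

    def test_class_boundaries(self):
        trains = comb_trains(1600.0, jitter=1e-4, seed=7)
        cond = tk.StimulusCondition(f0=400, fc=1600)
        zm = mt.z_metrics(trains, trains, cond, 0.0, 1600.0,
                          sr_sp_s=18.0, bf_hz=1850.0)
        assert zm.class_sr == "low" and zm.class_bf == "low"
        zm = mt.z_metrics(trains, trains, cond, 0.0, 1600.0,
                          sr_sp_s=18.5, bf_hz=1851.0)
        assert zm.class_sr == "high" and zm.class_bf == "high"

    def test_within_mode_uses_one_response(self, tfs1_400_1600):
        _, w_i = tfs1_400_1600
        fib = tk.FiberModel(sr_sp_s=10, driven_sp_s=150, bf_hz=1600,
                            tfs_gain=0.9, seed=1)
        ti = sp.simulate(fib, w_i, 20, seed=9)
        th = sp.SpikeTrainSet([np.array([0.1, 0.2, 0.3])])  # irrelevant
        zm = mt.z_metrics(th, ti, w_i.condition, 8.0, 1600.0, mode="within")
        z_unshifted = mt.vs_at(ti, 1600.0)[2]
        z_shifted = mt.vs_at(ti, 1632.0)[2]
        assert zm.tfs_log_z_ratio == pytest.approx(
            np.log10(z_unshifted / z_shifted))


class TestFMaxpeak:
    def test_construction_200_1600(self, uniform_trains):
        """A population locked to 1000 Hz puts the peak response there."""
        cond = tk.StimulusCondition(f0=200, fc=1600, filter_order=3, seed=2)
        w = tk.synthesize_complex(cond)
        pop = []
        for j, fib in enumerate(sp.population_preset(1000.0, 2, 2, seed=5)):
            pop.append(sp.simulate(fib, w, 20, seed=j))
        assert mt.f_maxpeak(pop, cond) == 1000.0

    def test_single_fiber_400_3200(self, uniform_trains):
        cond = tk.StimulusCondition(f0=400, fc=3200, filter_order=3, seed=3)
        w = tk.synthesize_complex(cond)
        fib = tk.FiberModel(sr_sp_s=0, driven_sp_s=200, bf_hz=2000,
                            tfs_gain=0.9, seed=0)
        trains = sp.simulate(fib, w, 20, seed=1)
        assert mt.f_maxpeak([trains], cond) == 2000.0

    def test_empty_population_rejected(self):
        cond = tk.StimulusCondition(f0=200, fc=1600)
        with pytest.raises(ValueError):
            mt.f_maxpeak([], cond)


class TestZPeakSearch:
    def test_locked_to_largest_shift(self):
        ladder = [0.0] + tk.shift_ladder(42.5, 7)
        trains = comb_trains(1000.0 + 0.425 * 200.0, jitter=5e-5, seed=8)
        best, z = mt.zpeak_shift_search(trains, 1000.0, ladder, 200.0)
        assert best == 42.5

    def test_harmonic_response_peaks_at_zero_shift(self):
        ladder = [0.0] + tk.shift_ladder(42.5, 7)
        trains = comb_trains(1000.0, jitter=5e-5, seed=9)
        best, _ = mt.zpeak_shift_search(trains, 1000.0, ladder, 200.0)
        assert best == 0.0

    def test_null_argmax_uniform_over_ladder(self, uniform_trains):
        """Unlocked trains pick each ladder entry equally often, provided
        the shifted frequencies are separated by more than the ~2.7 Hz
        resolution of a 375 ms window (sub-resolution shifts share
        correlated z values and split wins)."""
        from scipy.stats import chisquare

        ladder = [0.0] + tk.shift_ladder(42.5, 4)  # spacing >= 10.6 Hz
        counts = {p: 0 for p in ladder}
        for s in range(200):
            best, _ = mt.zpeak_shift_search(
                uniform_trains(n_reps=10, mean_count=40, seed=s),
                1000.0, ladder, 400.0)
            counts[best] += 1
        assert chisquare(list(counts.values())).pvalue > 0.01

    def test_ladder_must_include_zero(self):
        with pytest.raises(ValueError):
            mt.zpeak_shift_search(comb_trains(400.0), 400.0, [10.0], 200.0)
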