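"""Spike detection, selection rules, artifact exclusion, rate summaries."""

import numpy as np
import pytest
from scipy import integrate, signal as sps, stats

import spikemod as sm
from spikemod.errors import DegenerateDataError, ValidationError
from spikemod.preprocess import suggest_dense_threshold
from conftest import make_untuned_raster


def _trial(start, dur=5.0, finger=1, flag=False, label="pre"):
    return {"start_s": start, "duration_s": dur, "finger": finger,
            "movement_flag": flag, "session_label": label}


class TestThresholdCrossings:
    def test_injected_pulses_recovered(self):
        fs = 20_000.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(fs * 5))
        pulse_times = np.array([0.5, 1.2, 2.7, 3.9, 4.4])
        width = int(0.0004 * fs)
        for t in pulse_times:
            i = int(t * fs)
            x[i : i + width] -= 8.0  # ~ -8 x RMS, well past the -4.5 threshold
        events = sm.detect_threshold_crossings(sm.BroadbandSignal(samples=x, fs=fs))
        for t in pulse_times:
            assert np.min(np.abs(events - t)) < 1e-3

    def test_huge_threshold_gives_no_events(self):
        rng = np.random.default_rng(1)
        sig = sm.BroadbandSignal(samples=rng.standard_normal(50_000), fs=20_000.0)
        assert len(sm.detect_threshold_crossings(sig, k_rms=50.0)) == 0

    def test_flat_signal_warns_and_returns_empty(self):
        sig = sm.BroadbandSignal(samples=np.zeros(10_000), fs=20_000.0)
        with pytest.warns(UserWarning, match="flat"):
            events = sm.detect_threshold_crossings(sig)
        assert len(events) == 0

    def test_crossing_rate_matches_level_crossing_expectation(self):
        # Level-crossing oracle for a sampled stationary Gaussian process:
        # the expected down-crossing rate of level u is
        # fs * P(x_n > u, x_{n+1} < u), evaluated from the bivariate normal
        # with the process's lag-1 autocorrelation (the discrete-time form
        # of Rice's formula; the two agree as fs -> infinity).
        fs, f_max, hp, dur = 10_000.0, 2000.0, 250.0, 1000.0
        rng = np.random.default_rng(2)
        n = int(fs * dur)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        spec = np.fft.rfft(rng.standard_normal(n)) * (freqs <= f_max)
        x = np.fft.irfft(spec, n)
        x /= x.std()
        sig = sm.BroadbandSignal(samples=x, fs=fs)
        events = sm.detect_threshold_crossings(sig, hp_cutoff_hz=hp, k_rms=4.5,
                                               lockout_ms=0.01)
        # filtered synthesis spectrum: flat in band x |H_hp|^4 (filtfilt
        # squares the magnitude response)
        f = np.linspace(0, f_max, 4001)
        sos = sps.butter(4, hp, btype="highpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=f, fs=fs)
        S = np.abs(h) ** 4
        m0 = integrate.trapezoid(S, f)
        rho = integrate.trapezoid(S * np.cos(2 * np.pi * f / fs), f) / m0
        u = -4.5
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        predicted = fs * (stats.norm.cdf(u) - mvn.cdf([u, u]))
        observed = len(events) / dur
        assert abs(observed - predicted) / predicted < 0.20


class TestUnitSelection:
    def test_exact_threshold_rate_excluded(self):
        counts = np.zeros((2, 10_000), dtype=int)
        counts[0, :20] = 1   # exactly 2.0 Hz over 10 s
        counts[1, :21] = 1   # 2.1 Hz
        raster = sm.SpikeRaster(counts=counts, units=[sm.UnitMeta(unit_id=i) for i in range(2)])
        assert sm.select_units(raster, (0.0, 10.0)).tolist() == [1]

    @pytest.mark.parametrize("func,thr", [(sm.select_units, 2.0),
                                          (sm.filter_spontaneous_units, 0.5)])
    def test_agrees_with_bruteforce_oracle(self, func, thr):
        raster = make_untuned_raster(n_units=20, rate_hz=1.5, duration_s=30.0, seed=3)
        got = func(raster, (0.0, 30.0))
        expected = [i for i in range(20) if raster.counts[i].sum() / 30.0 > thr]
        assert got.tolist() == expected

    def test_spontaneous_boundary(self):
        counts = np.zeros((2, 10_000), dtype=int)
        counts[0, :5] = 1  # exactly 0.5 Hz
        counts[1, :6] = 1  # 0.6 Hz
        raster = sm.SpikeRaster(counts=counts, units=[sm.UnitMeta(unit_id=i) for i in range(2)])
        assert sm.filter_spontaneous_units(raster, (0.0, 10.0)).tolist() == [1]


class TestMovementTrials:
    def _raster_with_coincidence(self, n_active):
        counts = np.zeros((40, 20_000), dtype=int)
        counts[:n_active, 2500] = 1  # one bin inside the first trial
        return sm.SpikeRaster(counts=counts, units=[sm.UnitMeta(unit_id=i) for i in range(40)])

    def test_thirty_channels_flagging_boundary(self):
        trials = sm.make_trial_log([_trial(0.0), _trial(10.0)])
        flagged30 = sm.flag_movement_trials(self._raster_with_coincidence(30), trials)
        assert flagged30["movement_flag"].tolist() == [True, False]
        flagged29 = sm.flag_movement_trials(self._raster_with_coincidence(29), trials)
        assert flagged29["movement_flag"].tolist() == [False, False]

    def test_experimenter_flags_preserved(self):
        trials = sm.make_trial_log([_trial(0.0, flag=True), _trial(10.0)])
        out = sm.flag_movement_trials(self._raster_with_coincidence(0), trials)
        assert out["movement_flag"].tolist() == [True, False]

    def test_clean_synthetic_session_unflagged(self, tuned_session):
        raster, trials = tuned_session
        out = sm.flag_movement_trials(raster, trials)
        assert not out["movement_flag"].any()


class TestDenseEpochs:
    def test_quiet_raster_all_false(self, untuned_raster):
        mask = sm.exclude_dense_epochs(untuned_raster, count_threshold=1000)
        assert not mask.mask.any()

    def test_single_hot_bin_excludes_two_seconds(self):
        counts = np.zeros((5, 10_000), dtype=int)
        counts[:, 5000] = 100
        raster = sm.SpikeRaster(counts=counts, units=[sm.UnitMeta(unit_id=i) for i in range(5)])
        mask = sm.exclude_dense_epochs(raster, count_threshold=50)
        assert len(mask.runs) == 1
        assert mask.mask.sum() == 2000  # 1 s on each side of the hot 3 ms bin
        assert mask.mask[5000]

    def test_threshold_monotonicity(self, tuned_session):
        raster, _ = tuned_session
        loose = sm.exclude_dense_epochs(raster, count_threshold=12)
        tight = sm.exclude_dense_epochs(raster, count_threshold=6)
        # lowering the threshold never shrinks the excluded set
        assert np.all(tight.mask | ~loose.mask)

    def test_injected_bursts_covered(self):
        raster = make_untuned_raster(n_units=40, rate_hz=6.0, duration_s=120.0, seed=4)
        epochs = [(20.0, 21.5), (60.0, 61.0), (100.0, 102.0)]
        burst = sm.inject_movement_bursts(raster, epochs, burst_rate_hz=200.0, seed=5)
        thr = suggest_dense_threshold(raster, (0.0, 120.0))
        mask = sm.exclude_dense_epochs(burst, count_threshold=thr)
        covered = sum(mask.mask[int(a * 1000) : int(b * 1000)].sum() for a, b in epochs)
        total = sum(int(b * 1000) - int(a * 1000) for a, b in epochs)
        assert covered / total >= 0.95


class TestTrimTrialWindow:
    def test_five_second_trial_gives_three(self):
        a, b = sm.trim_trial_window(_trial(10.0, dur=5.0))
        assert (a, b) == (12.0, 15.0)

    def test_short_trial_rejected(self):
        with pytest.raises(ValidationError):
            sm.trim_trial_window(_trial(0.0, dur=2.0))

    @pytest.mark.parametrize("dur", [2.5, 4.0, 8.0])
    def test_window_length_is_duration_minus_two(self, dur):
        a, b = sm.trim_trial_window(_trial(1.0, dur=dur))
        assert b - a == pytest.approx(dur - 2.0)


class TestRunningTrend:
    def test_constant_rate_flat_trend(self):
        raster = make_untuned_raster(n_units=5, rate_hz=10.0, duration_s=900.0, seed=6)
        trend = sm.running_rate_trend(raster, window_min=5.0, step_s=30.0)
        assert np.all(np.abs(trend["rate_hz"] - 10.0) < 0.5)

    def test_step_change_recovered_in_normalised_trend(self):
        rng = np.random.default_rng(7)
        lam = np.full(1_200_000, 10.0 / 1000.0)
        lam[600_000:] *= 1.3
        counts = rng.poisson(lam, size=(6, len(lam)))
        raster = sm.SpikeRaster(counts=counts, units=[sm.UnitMeta(unit_id=i) for i in range(6)])
        trend = sm.running_rate_trend(raster, window_min=5.0, step_s=30.0,
                                      normalize_window=(0.0, 600.0))
        assert trend["rate_norm"].iloc[-1] == pytest.approx(1.3, abs=0.05)

    def test_fully_masked_interval_is_missing(self):
        raster = make_untuned_raster(n_units=3, rate_hz=5.0, duration_s=700.0, seed=8)
        mask = sm.ExclusionMask(mask=np.ones(raster.n_bins, dtype=bool))
        trend = sm.running_rate_trend(raster, mask, window_min=5.0, step_s=60.0)
        assert trend["rate_hz"].isna().all()


class TestConditionSummary:
    def test_analytic_mean_recovered(self):
        n = 25
        truth = sm.GroundTruth(
            baseline_rate_hz=np.full(n, 8.1), preferred_finger=np.zeros(n, int),
            tuning_gain=np.ones(n), drug_factor=np.full(n, 1.31),
            tuning_retained=np.zeros(n, bool), onset_tau_min=0.2,
        )
        tl = sm.SessionTimeline(t_drug_on=200.0, pre_window=(0.0, 200.0),
                                drug_window=(260.0, 600.0),
                                brushing_sessions=[("pre", 0.0, 1.0)])
        # drug window starts 5 tau after onset so the ramp is essentially done
        tl = sm.SessionTimeline(t_drug_on=200.0, pre_window=(0.0, 200.0),
                                drug_window=(200.0, 600.0),
                                brushing_sessions=[("pre", 0.0, 1.0)])
        raster = sm.simulate_spike_raster(truth, tl, sm.make_trial_log([]), seed=9)
        sub = sm.SessionTimeline(t_drug_on=200.0, pre_window=(0.0, 200.0),
                                 drug_window=(260.0, 600.0),
                                 brushing_sessions=[("pre", 0.0, 1.0)])
        s_pre, s_drug = sm.condition_rate_summary(raster, None, sub)
        assert s_pre.mean_hz == pytest.approx(8.1, rel=0.05)
        assert s_drug.mean_hz == pytest.approx(8.1 * 1.31, rel=0.05)

    def test_identical_windows_identical_summaries(self, untuned_raster):
        tl = sm.SessionTimeline(t_drug_on=30.0, pre_window=(0.0, 30.0),
                                drug_window=(30.0, 60.0),
                                brushing_sessions=[("pre", 0.0, 1.0)])
        a, _ = sm.condition_rate_summary(untuned_raster, None, tl)
        b, _ = sm.condition_rate_summary(untuned_raster, None, tl)
        assert np.array_equal(a.unit_rates_hz, b.unit_rates_hz)
        assert a.mean_hz == b.mean_hz

    def test_empty_unit_set_rejected(self, untuned_raster):
        tl = sm.SessionTimeline(t_drug_on=30.0, pre_window=(0.0, 30.0),
                                drug_window=(30.0, 60.0),
                                brushing_sessions=[("pre", 0.0, 1.0)])
        with pytest.raises(DegenerateDataError):
            sm.condition_rate_summary(untuned_raster, None, tl, np.array([], dtype=int))


class TestCompareRates:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        pre = rng.uniform(2, 10, 30)
        drug = pre * 1.2 + rng.normal(0, 0.5, 30)
        t, p = sm.compare_condition_rates(pre, drug)
        d = drug - pre
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(d) - 1)
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.uniform(1, 5, 20), rng.uniform(1, 5, 20)
        t_ab, _ = sm.compare_condition_rates(a, b)
        t_ba, _ = sm.compare_condition_rates(b, a)
        assert t_ab == pytest.approx(-t_ba)

    def test_identical_vectors_degenerate(self):
        x = np.arange(1.0, 11.0)
        with pytest.raises(DegenerateDataError):
            sm.compare_condition_rates(x, x)

    def test_large_effect_significant(self):
        rng = np.random.default_rng(12)
        pre = rng.uniform(4, 8, 50)
        t, p = sm.compare_condition_rates(pre, pre * 1.5 + rng.normal(0, 0.2, 50))
        assert p < 0.001 and t > 0


class TestRateChangeHistogram:
    def test_counts_conserved_and_unchanged_on_axis(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        h, xe, _ = sm.rate_change_histogram(pre, pre, change_bins=5, rate_bins=5)
        assert h.sum() == 4
        # all mass in the bin containing change = 0
        col = np.searchsorted(xe, 0.0, side="right") - 1
        col = min(col, h.shape[0] - 1)
        assert h[col].sum() == 4

    def test_fraction_increasing_matches_ground_truth(self):
        truth = sm.sample_population(
            sm.PopulationConfig(n_units=4000, frac_rate_increase=0.8), 13
        )
        pre = truth.baseline_rate_hz
        drug = pre * truth.drug_factor
        h, xe, _ = sm.rate_change_histogram(pre, drug, change_bins=41, rate_bins=10)
        frac_right = h[xe[:-1] >= 0].sum() / h.sum()
        assert frac_right == pytest.approx(0.8, abs=0.03)
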