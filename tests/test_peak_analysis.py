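"""Change-point segmentation, Gaussian peak fits, single-trial detection,
and session peak statistics."""

import numpy as np
import pytest

import licktime as lt
from licktime.io_events import LickTrain
from licktime.peak_analysis import (FitError, Peak, PeakConfig,
                                    changepoints_mean, detect_peak,
                                    detect_session_peaks, fit_gaussian,
                                    peak_shift_curve, peak_stats,
                                    window_start_for_trial)
from licktime.synthetic import LickModelParams, StimEffectParams, simulate_licking

from conftest import make_probe_table, metronome
from oracle_utils import (exhaustive_changepoints, gaussian_envelope_licks,
                          grid_search_gaussian_fit, planted_shift_signal,
                          skewness_moment_formula)


class TestChangepoints:
    def test_single_step_found_rising(self, rng):
        sig = np.r_[np.zeros(50), np.full(50, 5.0)] + rng.normal(0, 0.2, 100)
        cps = changepoints_mean(sig)
        rising = [i for i, d in cps if d == "rising"]
        assert len(rising) == 1 and abs(rising[0] - 50) <= 1

    def test_constant_signal_yields_empty(self):
        assert changepoints_mean(np.full(100, 2.0)) == []

    def test_boxcar_matches_exhaustive_oracle(self):
        sig = np.zeros(100)
        sig[40:70] = 6.0
        got = sorted(i for i, _ in changepoints_mean(sig))
        assert got == exhaustive_changepoints(sig) == [40, 70]

    def test_random_planted_signals_match_oracle(self):
        rng = np.random.default_rng(2024)
        agree = 0
        n_sig = 60
        for _ in range(n_sig):
            sig, _ = planted_shift_signal(rng)
            got = sorted(i for i, _ in changepoints_mean(sig))
            want = exhaustive_changepoints(sig)
            if len(got) == len(want) and all(abs(a - b) <= 1
                                             for a, b in zip(got, want)):
                agree += 1
        assert agree / n_sig >= 0.95

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            changepoints_mean(np.arange(5.0))


class TestFitGaussian:
    def test_exact_samples_recovered(self):
        t = np.linspace(5, 15, 60)
        y = 6.0 * np.exp(-((t - 10.0) ** 2) / (2 * 1.5**2))
        a, mu, sd = fit_gaussian(t, y)
        assert a == pytest.approx(6.0, abs=1e-6)
        assert mu == pytest.approx(10.0, abs=1e-6)
        assert sd == pytest.approx(1.5, abs=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        t = np.linspace(6, 14, 80)
        y = 5.0 * np.exp(-((t - 10.0) ** 2) / (2 * 1.2**2)) + rng.normal(0, 0.3, 80)
        _, mu, _ = fit_gaussian(t, y)
        _, mu_oracle, _ = grid_search_gaussian_fit(
            t, y, np.arange(8, 12, 0.02), np.arange(0.5, 3.0, 0.05))
        assert abs(mu - 10.0) < 0.2
        assert abs(mu - mu_oracle) < 0.1

    def test_all_zero_segment_fails(self):
        with pytest.raises(FitError):
            fit_gaussian(np.linspace(0, 5, 20), np.zeros(20))


def _probe_bundle(n, lick_params=None, stim=None, laser_onset=None, seed=1):
    trials = make_probe_table(n, laser_onset=laser_onset)
    b = simulate_licking(trials, lick_params or LickModelParams(), stim, seed=seed)
    return trials, b


class TestDetectPeak:
    def test_noiseless_gaussian_envelope_bout(self):
        # deterministic inverse-intensity lick train, centre 10 s
        ts = gaussian_envelope_licks(10.0, 1.2, 7.0, 0.0, 20.0)
        # anticipatory/consummatory context so the window starts on licking
        ts = np.sort(np.r_[metronome(-3.0, 2.0, 6.0), ts])
        licks = lt.filter_licks(ts + 100.0)
        p = detect_peak(licks, 100.0)
        assert p is not None
        assert p.peak_time == pytest.approx(10.0, abs=0.2)

    def test_flat_low_rate_background_yields_none(self):
        licks = LickTrain(np.arange(0.0, 30.0, 1.0))   # 1 Hz forever
        assert detect_peak(licks, 0.0) is None

    def test_short_bout_yields_none(self):
        ts = np.r_[metronome(-3.0, 2.0, 6.0), metronome(9.5, 11.0, 7.0)]
        licks = lt.filter_licks(np.asarray(ts) + 50.0)
        assert detect_peak(licks, 50.0) is None

    def test_long_bout_accepted_short_rejected(self):
        for dur, ok in [(1.6, False), (2.6, True)]:
            ts = np.r_[metronome(-3.0, 2.0, 6.0),
                       metronome(10.0 - dur / 2, 10.0 + dur / 2, 7.0)]
            licks = lt.filter_licks(np.asarray(ts) + 50.0)
            got = detect_peak(licks, 50.0)
            assert (got is not None) == ok

    def test_translation_equivariance(self, rng):
        trials, b = _probe_bundle(1, seed=9)
        reward = float(trials.df.reward_time.iloc[0])
        p0 = detect_peak(b.licks, reward)
        delta = 7.25
        p1 = detect_peak(b.licks.shifted(delta), reward + delta)
        assert p0 is not None and p1 is not None
        assert p1.peak_time == pytest.approx(p0.peak_time, abs=1e-9)
        assert p1.start == pytest.approx(p0.start, abs=1e-9)

    def test_mean_peak_time_converges_to_generator_center(self):
        trials, b = _probe_bundle(200, seed=11)
        peaks = detect_session_peaks(b)
        times = [p.peak_time for p in peaks.values() if p is not None]
        assert len(times) > 150
        assert abs(np.mean(times) - 10.0) < 0.3

    def test_window_start_rules(self):
        trials = make_probe_table(2, laser_onset=5.0, laser_every=2)
        laser_tr = next(trials.itertrials())
        plain_tr = list(trials.itertrials())[1]
        assert window_start_for_trial(laser_tr, "d1_evoke") == 5.0
        assert window_start_for_trial(laser_tr, "a2a_suppress", "recovery") == 6.0
        assert window_start_for_trial(laser_tr, "a2a_suppress", "initiation") == 0.0
        assert window_start_for_trial(plain_tr, "d1_evoke") == 0.0


class TestPeakStats:
    def _peaks_and_licks(self, centers, halfwidth=2.0, sym=True):
        peaks, ts, rewards = [], [], {}
        for tid, c in enumerate(centers):
            r = 100.0 * (tid + 1)
            rewards[tid] = r
            offs = np.linspace(-halfwidth, halfwidth, 23)
            if not sym:
                # dense mass left of centre plus a sparse right tail
                offs = np.r_[np.linspace(-halfwidth, -halfwidth / 2, 40),
                             np.linspace(-halfwidth / 2, halfwidth, 12)]
            ts += (r + c + offs).tolist()
            peaks.append(Peak(tid, c - halfwidth, c + halfwidth, c, 6.0, 1.0, 0))
        return peaks, lt.filter_licks(np.sort(ts)), rewards

    def test_symmetric_licks_zero_skew_and_width(self):
        peaks, licks, rewards = self._peaks_and_licks([10.0, 10.5, 9.5])
        st = peak_stats(peaks, licks, rewards)
        assert st.mean_width == pytest.approx(4.0)
        assert abs(st.skewness) < 0.05
        assert st.n_trials_used == 3 and st.n_discarded == 0

    def test_right_tailed_skew_matches_moment_formula(self):
        peaks, licks, rewards = self._peaks_and_licks([10.0, 10.0], sym=False)
        st = peak_stats(peaks, licks, rewards)
        pooled = []
        for p in peaks:
            r = rewards[p.trial_id]
            pooled.append(licks.in_window(r + p.start, r + p.end) - r)
        assert st.skewness == pytest.approx(
            skewness_moment_formula(np.concatenate(pooled)), abs=1e-12)
        assert st.skewness > 0

    def test_peak_shift_against_baseline(self):
        peaks, licks, rewards = self._peaks_and_licks([10.0, 10.0])
        base = [Peak(9, 3.0, 7.0, 5.0, 6.0, 1.0, 0)]
        st = peak_stats(peaks, licks, rewards, baseline_peaks=base)
        assert st.peak_shift == pytest.approx(5.0)
        same = peak_stats(peaks, licks, rewards, baseline_peaks=peaks)
        assert same.peak_shift == pytest.approx(0.0)

    def test_no_valid_peaks_is_an_error(self):
        with pytest.raises(ValueError):
            peak_stats([None], lt.filter_licks([1.0]), {})


class TestPeakShiftCurve:
    def test_reset_sessions_recover_stimulation_onsets(self):
        bundles = []
        for onset in (0.0, 3.0, 5.0):
            trials = make_probe_table(60, laser_onset=(onset if onset > 0 else 1e-9),
                                      laser_every=2)
            if onset == 0.0:
                # onset exactly at reward: encode as tiny positive then zero out
                df = trials.df.copy()
                df.loc[df.laser_onset_rel.notna(), "laser_onset_rel"] = 0.0
                trials = lt.TrialTable(df)
            stim = StimEffectParams(mode="d1_evoke", timing_mode="reset")
            b = simulate_licking(trials, LickModelParams(peak_center_sd=0.5),
                                 stim, seed=int(13 + onset))
            bundles.append(b)
        curve = peak_shift_curve(bundles)
        assert len(curve) == 3
        got = dict(zip(curve.stim_onset, curve.peak_shift))
        for onset in (0.0, 3.0, 5.0):
            assert got[onset] == pytest.approx(onset, abs=0.5)
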