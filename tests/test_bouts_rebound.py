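"""Bout onsets, stimulation metrics, rebound classification, quartiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import licktime as lt
from licktime.bouts_rebound import (bout_onsets, canonical_rebound_label,
                                    classify_rebound_trial, classify_session,
                                    delta_lick_rate, evoke_latency,
                                    latency_summary, post_offset_count,
                                    quartile_analysis, rebound_latency,
                                    rebound_session_half_fractions,
                                    stim_trial_metrics)
from licktime.io_events import LickTrain
from licktime.synthetic import (LickModelParams, StimEffectParams,
                                simulate_licking)

from conftest import make_fixed_table, make_probe_table, metronome


def _onsets_oracle(ts):
    out = []
    for i, t in enumerate(ts):
        if i == 0 or t - ts[i - 1] >= 1.0:
            out.append(t)
    return out


class TestBoutOnsets:
    @pytest.mark.parametrize("ts,expected", [
        ([0, 0.2, 0.4, 3.0, 3.2], [0, 3.0]),
        ([5.0], [5.0]),
        ([], []),
    ])
    def test_examples(self, ts, expected):
        got = bout_onsets(LickTrain(np.asarray(ts, dtype=float)))
        assert got.onset_times.tolist() == expected

    def test_matches_gap_scan_oracle(self, rng):
        ts = np.sort(rng.uniform(0, 60, 300))
        ts = lt.filter_licks(ts).timestamps
        got = bout_onsets(LickTrain(ts)).onset_times
        assert got.tolist() == _onsets_oracle(ts.tolist())

    @given(st.floats(-50, 50))
    @settings(deadline=None, max_examples=25)
    def test_time_shift_equivariance(self, delta):
        ts = np.array([0.0, 0.3, 0.6, 2.1, 2.3, 5.0])
        base = bout_onsets(LickTrain(ts)).onset_times
        shifted = bout_onsets(LickTrain(ts + delta)).onset_times
        assert np.allclose(shifted, base + delta)


def _laser_session(stim_rate=8.0, base_rate=2.0):
    """Hand-built fixed-trial session: laser trials lick at stim_rate during
    the laser second, no-laser trials at base_rate in the same window."""
    trials = make_fixed_table(8, laser_onset=-5.0, laser_every=2)
    ts = []
    for tr in trials.itertrials():
        w0 = tr.reward_time - 5.0
        rate = stim_rate if not np.isnan(tr.laser_onset_rel) else base_rate
        ts += metronome(w0 + 1e-4, w0 + 1.0, rate)
    return lt.SessionBundle(lt.filter_licks(ts), trials, {"interval": 10.0})


class TestDeltaLickRate:
    def test_hand_computed_difference(self):
        table, group = delta_lick_rate(_laser_session(8.0, 2.0))
        assert group == pytest.approx(6.0)
        assert np.allclose(table.delta_rate, 6.0)

    def test_identical_behavior_gives_zero(self):
        table, group = delta_lick_rate(_laser_session(4.0, 4.0))
        assert group == pytest.approx(0.0)

    def test_requires_matched_baseline(self):
        trials = make_fixed_table(4, laser_onset=-5.0, laser_every=1)
        bundle = lt.SessionBundle(lt.filter_licks([1.0]), trials)
        with pytest.raises(ValueError):
            delta_lick_rate(bundle)

    def test_control_sessions_have_null_contrast(self):
        # eYFP-style: laser trials carry no injected effect
        trials = make_fixed_table(60, laser_onset=-1.0, laser_every=2)
        b = simulate_licking(trials, LickModelParams(anticipation_onset_sd=0.5),
                             StimEffectParams(mode="none"), seed=17)
        _, group = delta_lick_rate(b)
        assert abs(group) < 1.0

    def test_suppression_of_anticipatory_licking(self):
        # full suppression of ~6 Hz anticipatory licking -> delta ~ -6
        trials = make_fixed_table(100, laser_onset=-1.0, laser_every=2)
        p = LickModelParams(bout_frequency=6.0, anticipation_onset_mean=4.0,
                            anticipation_onset_sd=0.0, baseline_rate=0.0)
        b = simulate_licking(trials, p, StimEffectParams(mode="a2a_suppress",
                                                         p_rebound=0.0), seed=18)
        _, group = delta_lick_rate(b)
        assert group == pytest.approx(-6.0, abs=0.5)


class TestLatenciesAndCounts:
    def test_evoke_latency_examples(self):
        on = np.array([10.3, 12.0])
        o = bout_onsets(LickTrain(on))
        assert evoke_latency(o, 10.0) == pytest.approx(0.3)
        assert np.isnan(evoke_latency(o, 5.0))       # exclusion rule

    def test_rebound_latency_window_rule(self):
        o = bout_onsets(LickTrain(np.array([14.5])))
        assert rebound_latency(o, 14.0) == pytest.approx(0.5)
        o_late = bout_onsets(LickTrain(np.array([17.5])))
        assert np.isnan(rebound_latency(o_late, 14.0))

    def test_latency_variance_hand_computed(self):
        s = latency_summary([0.4, 0.6])
        assert s["variance"] == pytest.approx(0.02)
        assert s["mean"] == pytest.approx(0.5)

    def test_post_offset_count(self):
        licks = LickTrain(np.array([10.1, 10.2, 10.5, 10.9, 11.5]))
        assert post_offset_count(licks, 10.0) == 4
        assert post_offset_count(licks, 20.0) == 0

    def test_generator_latency_distributions_recovered(self):
        trials = make_fixed_table(400, laser_onset=-5.0, laser_every=2)
        stim = StimEffectParams(mode="d1_evoke")
        b = simulate_licking(trials, LickModelParams(baseline_rate=0.0),
                             stim, seed=19)
        m = stim_trial_metrics(b)
        lat = m.evoke_latency.dropna()
        mu, sd = stim.evoke_latency_map[10.0]
        assert len(lat) > 150
        assert abs(lat.mean() - mu) < 2 * sd / np.sqrt(len(lat)) + 0.01

    def test_rebound_latency_recovery_and_persist_count(self):
        trials = make_fixed_table(400, laser_onset=-5.0, laser_every=2,
                                  laser_frequency=25.0)
        stim = StimEffectParams(mode="a2a_suppress", p_rebound=1.0)
        # anticipation kept clear of the post-offset window so the first
        # onset after offset is the rebound itself
        p = LickModelParams(baseline_rate=0.0, anticipation_onset_mean=2.0,
                            anticipation_onset_sd=0.3)
        b = simulate_licking(trials, p, stim, seed=20)
        m = stim_trial_metrics(b)
        lat = m.rebound_latency.dropna()
        mu, sd = stim.rebound_latency_map[25.0]
        assert abs(lat.mean() - mu) < 2 * sd / np.sqrt(len(lat)) + 0.02


class TestReboundClassification:
    def _trial(self, reward=100.0):
        t = make_probe_table(1, laser_onset=5.0, start=reward)
        return next(t.itertrials())

    def _licks(self, *times):
        return lt.filter_licks(np.asarray(times))

    def test_recovery_rule(self):
        tr = self._trial()
        stim_on = 105.0
        licks = self._licks(stim_on + 1.2, stim_on + 1.2 + 4.0)
        assert classify_rebound_trial(licks, tr) == "recovery"

    def test_initiation_rule(self):
        tr = self._trial()
        licks = self._licks(106.2)
        assert classify_rebound_trial(licks, tr) == "initiation"

    def test_no_rebound_rule(self):
        tr = self._trial()
        licks = self._licks(107.5, 111.0)
        assert classify_rebound_trial(licks, tr) == "no_rebound"

    def test_requires_probe_with_midtrial_laser(self):
        fixed = next(make_fixed_table(1, laser_onset=-5.0, laser_every=1).itertrials())
        with pytest.raises(ValueError):
            classify_rebound_trial(self._licks(1.0), fixed)
        plain = next(make_probe_table(1).itertrials())
        with pytest.raises(ValueError):
            classify_rebound_trial(self._licks(1.0), plain)

    def test_absorption_alias_accepted(self):
        assert canonical_rebound_label("absorption") == "initiation"
        with pytest.raises(ValueError):
            canonical_rebound_label("sideways")

    def test_labels_partition_classified_trials(self):
        trials = make_probe_table(40, laser_onset=5.0, laser_every=2)
        stim = StimEffectParams(mode="a2a_suppress", timing_mode="pause_plus_rebound")
        b = simulate_licking(trials, LickModelParams(), stim, seed=23)
        cls = classify_session(b)
        n_laser = int((trials.df.laser_onset_rel > 0).sum())
        assert len(cls) == n_laser
        assert cls.label.isin(["recovery", "initiation", "no_rebound"]).all()


class TestQuartiles:
    def test_forty_laser_trials_split_into_tens(self):
        trials = make_fixed_table(80, laser_onset=-5.0, laser_every=2)
        b = simulate_licking(trials, LickModelParams(),
                             StimEffectParams(mode="d1_evoke"), seed=25)
        m = stim_trial_metrics(b)
        assert m.quartile.value_counts().tolist() == [10, 10, 10, 10]

    def test_constant_metric_equal_means(self):
        b = _laser_session(8.0, 2.0)
        q = quartile_analysis(b, "delta_rate")
        assert np.allclose(q["mean"], q["mean"].iloc[0])

    def test_too_few_laser_trials_rejected(self):
        trials = make_fixed_table(4, laser_onset=-5.0, laser_every=2)
        ts = [t for tr in trials.itertrials()
              for t in metronome(tr.reward_time - 5, tr.reward_time - 4, 6.0)]
        b = lt.SessionBundle(lt.filter_licks(ts), trials)
        with pytest.raises(ValueError):
            quartile_analysis(b, "delta_rate")

    def test_satiety_increases_evoke_latency_across_quartiles(self):
        trials = make_fixed_table(160, laser_onset=-5.0, laser_every=2)
        b = simulate_licking(trials, LickModelParams(satiety_slope=1.0,
                                                     baseline_rate=0.0),
                             StimEffectParams(mode="d1_evoke"), seed=26)
        q = quartile_analysis(b, "evoke_latency").set_index("quartile")["mean"]
        assert q.loc[4] > q.loc[1]


class TestHalfFractions:
    def test_all_recovery(self):
        out = rebound_session_half_fractions(["recovery"] * 8)
        rec = out[out.label == "recovery"]
        assert np.allclose(rec.fraction, 1.0)
        assert np.allclose(out.groupby("half").fraction.sum(), 1.0)

    def test_fractions_sum_to_one_per_half(self):
        labels = ["recovery", "initiation", "no_rebound", "recovery",
                  "no_rebound", "initiation", "initiation"]
        out = rebound_session_half_fractions(labels)
        assert np.allclose(out.groupby("half").fraction.sum(), 1.0)

    def test_empty_half_rejected(self):
        with pytest.raises(ValueError):
            rebound_session_half_fractions(["recovery"])

    def test_satiety_shrinks_recovery_fraction_late_in_session(self):
        trials = make_probe_table(160, laser_onset=5.0)
        stim = StimEffectParams(mode="a2a_suppress",
                                timing_mode="pause_plus_rebound")
        b = simulate_licking(trials, LickModelParams(satiety_slope=0.9),
                             stim, seed=27)
        cls = classify_session(b)
        out = rebound_session_half_fractions(list(cls.label))
        rec = out[out.label == "recovery"].set_index("half")["fraction"]
        assert rec.loc[2] < rec.loc[1]
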