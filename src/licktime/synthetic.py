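"""Synthetic session generator for the fixed-time licking task.

Real sessions from this task are not publicly deposited, so every analysis
stage in this package is exercised against simulated sessions that carry the
statistical structure those analyses assume:

* a trial scheduler reproducing the task program — blocks of three plain
  fixed-time trials followed by a decision point drawn 30/30/30 (laser on a
  normal trial / laser on a peak-probe trial / plain peak-probe trial) with a
  10 % redraw, and gamma-distributed probe durations;
* naturalistic licking built from bouts — a jittered metronome within bouts
  (4–8 Hz), anticipatory ramping before each reward, consummatory licking
  after it, and on probe trials a peak bout centred near the trained
  interval;
* injectable optogenetic effects — direct-pathway evoked licking (capped at
  10 Hz, latency falling with stimulation frequency, persistence past
  offset) and indirect-pathway suppression with post-offset rebound — plus
  clock perturbations (reset, pause) expressed as displaced peak bouts.

Every simulated session records its per-trial ground truth so detection
stages can be scored by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .io_events import LickTrain, SessionBundle, TrialTable, TRIAL_COLUMNS, filter_licks

#: shortest credible inter-lick interval in a bout; the lick pattern
#: generator tops out near 10 Hz, so ILIs are truncated here.
MIN_BOUT_ILI = 0.05

TIMING_MODES = ("none", "reset", "pause", "pause_plus_rebound")
STIM_MODES = ("none", "d1_evoke", "a2a_suppress")


@dataclass
class TaskParams:
    """Task-program parameters for the trial scheduler."""

    interval: float = 10.0
    n_trials: int = 100
    p_laser_normal: float = 0.3
    p_laser_peak: float = 0.3
    p_peak_plain: float = 0.3
    p_redraw: float = 0.1
    probe_base: float = 30.0
    probe_gamma_shape: float = 2.5
    probe_gamma_scale: float = 4.0
    laser_onset_normal: float = -5.0   # s relative to reward on normal trials
    laser_onset_peak: float = 5.0      # s relative to initiating reward on probes
    laser_frequency: float = 25.0
    laser_duration: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        total = self.p_laser_normal + self.p_laser_peak + self.p_peak_plain + self.p_redraw
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"decision probabilities sum to {total}, expected 1")
        if self.probe_gamma_shape <= 0 or self.probe_gamma_scale <= 0:
            raise ConfigError("gamma shape and scale must be positive")
        if self.interval <= 0 or self.n_trials < 0:
            raise ConfigError("interval must be positive and n_trials >= 0")
        if self.laser_duration <= 0:
            raise ConfigError("laser_duration must be positive")


@dataclass
class LickModelParams:
    """Bout-level licking model.

    Licking is a union of bouts; within a bout the tongue is a jittered
    metronome (ILI = 1/frequency + Gaussian jitter, truncated at
    ``MIN_BOUT_ILI``).  Anticipatory bouts start ``|N(mean, sd)|`` seconds
    before reward and run at ~5.5 Hz; consummatory bouts follow each reward
    at ~7 Hz; probe trials add a peak bout whose centre is drawn around the
    trained interval.  ``satiety_slope`` linearly inflates stimulation
    latencies and deflates rebound probability across the session.
    """

    bout_frequency: float = 5.5
    consummatory_frequency: float = 7.0
    ili_jitter_sd: float = 0.01
    anticipation_onset_mean: float = 3.0
    anticipation_onset_sd: float = 1.0
    consummatory_duration: float = 2.0
    peak_bout_center: Optional[float] = None   # None -> task interval
    peak_center_sd: float = 1.0
    peak_bout_halfwidth: float = 2.0
    baseline_rate: float = 0.1
    satiety_slope: float = 0.0
    seed: Optional[int] = None

    def validate(self) -> None:
        for f in (self.bout_frequency, self.consummatory_frequency):
            if not 0 < f <= 12:
                raise ConfigError(f"bout frequency {f} outside (0, 12] Hz")
        for sd in (self.ili_jitter_sd, self.anticipation_onset_sd, self.peak_center_sd):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        if self.baseline_rate < 0 or self.peak_bout_halfwidth <= 0:
            raise ConfigError("baseline_rate >= 0 and peak_bout_halfwidth > 0 required")


def _default_evoked_frequency_map() -> dict:
    # stimulation Hz -> evoked lick Hz; saturates at the 10 Hz CPG cap
    return {5.0: 7.0, 10.0: 9.5, 25.0: 10.0, 50.0: 10.0}


def _default_evoke_latency_map() -> dict:
    # stimulation Hz -> (mean, sd) onset latency; falls with frequency
    return {5.0: (0.45, 0.08), 10.0: (0.30, 0.06), 25.0: (0.15, 0.04), 50.0: (0.10, 0.03)}


def _default_rebound_latency_map() -> dict:
    # stimulation Hz -> (mean, sd) post-offset rebound latency; mean and
    # spread both shrink with frequency
    return {5.0: (0.80, 0.25), 10.0: (0.60, 0.15), 25.0: (0.40, 0.08), 50.0: (0.25, 0.04)}


@dataclass
class StimEffectParams:
    """Injectable optogenetic effects.

    ``mode`` selects the perturbed pathway: ``d1_evoke`` adds an evoked bout
    during stimulation (plus ``post_offset_persist`` seconds beyond offset);
    ``a2a_suppress`` deletes licking during stimulation and, with probability
    ``p_rebound``, injects a rebound bout after offset.  ``timing_mode``
    expresses the clock-level consequence on probe trials: ``reset``
    re-centres the peak bout at stimulation onset + interval; ``pause``
    delays it by the stimulation duration; ``pause_plus_rebound`` delays it
    by stimulation plus rebound duration on rebound-recovery trials while
    rebound-initiation trials start the peak bout at the rebound itself.
    """

    mode: str = "d1_evoke"
    evoked_frequency_map: dict = field(default_factory=_default_evoked_frequency_map)
    evoke_latency_map: dict = field(default_factory=_default_evoke_latency_map)
    post_offset_persist: float = 0.5
    rebound_latency_map: dict = field(default_factory=_default_rebound_latency_map)
    rebound_window: float = 3.0
    rebound_bout_duration: float = 1.0
    p_rebound: float = 2.0 / 3.0
    p_initiation_given_rebound: float = 0.5
    timing_mode: str = "none"

    def validate(self) -> None:
        if self.mode not in STIM_MODES:
            raise ConfigError(f"unknown stim mode {self.mode!r}")
        if self.timing_mode not in TIMING_MODES:
            raise ConfigError(f"unknown timing_mode {self.timing_mode!r}")
        if any(v > 10.0 for v in self.evoked_frequency_map.values()):
            raise ConfigError("evoked lick frequencies must be <= 10 Hz")
        for m in (self.evoke_latency_map, self.rebound_latency_map):
            if any(mu < 0 or sd < 0 for mu, sd in m.values()):
                raise ConfigError("latencies and their sds must be >= 0")
        if not 0 <= self.p_rebound <= 1 or not 0 <= self.p_initiation_given_rebound <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# scheduler


def simulate_scheduler(task: TaskParams) -> TrialTable:
    """Run the task program and return the resulting trial table.

    After three consecutive plain fixed-time trials the program enters a
    decision point drawn 0.3/0.3/0.3 (laser-normal / laser-peak /
    plain-peak) with 0.1 probability of an immediate redraw, so each outcome
    is realised with probability 0.3 * sum(0.1^k) = 1/3.  Probe durations are
    ``probe_base + Gamma(shape, scale)`` seconds, and the consecutive-reward
    counter restarts after each probe's terminal reward.  Deterministic under
    a fixed seed.
    """
    task.validate()
    rng = np.random.default_rng(task.seed)
    rows = []
    t = task.interval          # first reward one interval into the session
    consec = 0
    for tid in range(task.n_trials):
        if consec < 3:
            rows.append(_trial_row(tid, t, "fixed"))
            consec += 1
            t += task.interval
            continue
        # decision point; redraw until a terminal outcome
        while True:
            u = rng.random()
            if u >= task.p_redraw:
                break
        u = (u - task.p_redraw) / (1.0 - task.p_redraw)  # uniform over outcomes
        third = 1.0 / 3.0
        if u < third:
            rows.append(
                _trial_row(tid, t, "fixed",
                           laser_onset_rel=task.laser_onset_normal,
                           laser_duration=task.laser_duration,
                           laser_frequency=task.laser_frequency)
            )
            t += task.interval
        else:
            probe = task.probe_base + rng.gamma(task.probe_gamma_shape,
                                                task.probe_gamma_scale)
            laser = u < 2 * third
            rows.append(
                _trial_row(tid, t, "peak",
                           probe_duration=probe,
                           laser_onset_rel=task.laser_onset_peak if laser else np.nan,
                           laser_duration=task.laser_duration if laser else np.nan,
                           laser_frequency=task.laser_frequency if laser else np.nan)
            )
            t += probe           # terminal reward starts the next trial
        consec = 0
    return TrialTable(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def _trial_row(tid, reward_time, kind, probe_duration=np.nan,
               laser_onset_rel=np.nan, laser_duration=np.nan,
               laser_frequency=np.nan) -> dict:
    return {
        "trial_id": tid,
        "reward_time": reward_time,
        "kind": kind,
        "laser_onset_rel": laser_onset_rel,
        "laser_duration": laser_duration,
        "laser_frequency": laser_frequency,
        "probe_duration": probe_duration,
    }


# ---------------------------------------------------------------------------
# licking


def _metronome(rng, start: float, stop: float, freq: float, jitter_sd: float) -> list:
    """Jittered metronome lick times in [start, stop)."""
    out = []
    t = start
    while t < stop:
        out.append(t)
        ili = 1.0 / freq + rng.normal(0.0, jitter_sd)
        t += max(ili, MIN_BOUT_ILI)
    return out


def _map_lookup(table: dict, freq: float):
    if freq in table:
        return table[freq]
    key = min(table, key=lambda k: abs(k - freq))
    return table[key]


def simulate_licking(trials: TrialTable,
                     lick: Optional[LickModelParams] = None,
                     stim: Optional[StimEffectParams] = None,
                     seed: Optional[int] = None,
                     session_id: str = "synthetic",
                     interval: float = 10.0) -> SessionBundle:
    """Generate a session's lick train over a trial table.

    One master seed derives an independent substream per trial, so any trial
    can be regenerated in isolation.  The returned bundle carries a
    per-trial ground-truth table (see :func:`ground_truth`) and always
    passes the ingest invariants (post-filter ILIs >= 8 ms).
    """
    lick = lick or LickModelParams()
    stim = stim or StimEffectParams(mode="none")
    lick.validate()
    stim.validate()
    if seed is None:
        seed = lick.seed if lick.seed is not None else 0

    df = trials.df
    n = len(df)
    streams = np.random.SeedSequence(seed).spawn(max(n, 1))
    peak_center = lick.peak_bout_center if lick.peak_bout_center is not None else interval

    all_licks: list = []
    suppress_windows: list = []
    truth_rows: list = []

    for i, tr in enumerate(df.itertuples(index=False)):
        rng = np.random.default_rng(streams[i])
        sat = 1.0 + lick.satiety_slope * (i / max(n - 1, 1))
        reward = tr.reward_time
        is_peak = tr.kind == "peak"
        trial_end = reward + (tr.probe_duration if is_peak else interval)
        has_laser = not np.isnan(tr.laser_onset_rel)
        laser_on = reward + tr.laser_onset_rel if has_laser else np.nan
        laser_off = laser_on + tr.laser_duration if has_laser else np.nan

        # anticipatory bout ramping into this trial's reward
        ant_onset = reward - abs(rng.normal(lick.anticipation_onset_mean,
                                            lick.anticipation_onset_sd))
        all_licks += _metronome(rng, ant_onset, reward,
                                lick.bout_frequency, lick.ili_jitter_sd)
        # consummatory bout after the (initiating) reward
        all_licks += _metronome(rng, reward + 0.1,
                                reward + lick.consummatory_duration,
                                lick.consummatory_frequency, lick.ili_jitter_sd)
        # sparse baseline licking across the trial
        n_base = rng.poisson(lick.baseline_rate * (trial_end - reward))
        all_licks += list(rng.uniform(reward, trial_end, size=n_base))

        true_center = np.nan
        true_evoke = np.nan
        true_rebound = np.nan
        pattern = ""
        peak_start_override = np.nan

        if is_peak:
            true_center = rng.normal(reward + peak_center, lick.peak_center_sd)

        if has_laser and stim.mode == "d1_evoke":
            freq = tr.laser_frequency
            mu, sd = _map_lookup(stim.evoke_latency_map, freq)
            true_evoke = abs(rng.normal(mu * sat, sd))
            evoked_f = min(_map_lookup(stim.evoked_frequency_map, freq), 10.0)
            all_licks += _metronome(rng, laser_on + true_evoke,
                                    laser_off + stim.post_offset_persist,
                                    evoked_f, lick.ili_jitter_sd)
            if is_peak and stim.timing_mode == "reset":
                true_center = rng.normal(laser_on + interval, lick.peak_center_sd)

        if has_laser and stim.mode == "a2a_suppress":
            suppress_windows.append((laser_on, laser_off))
            freq = tr.laser_frequency
            p_reb = stim.p_rebound * max(0.0, 1.0 - lick.satiety_slope
                                         * (i / max(n - 1, 1)))
            if rng.random() < p_reb:
                mu, sd = _map_lookup(stim.rebound_latency_map, freq)
                true_rebound = abs(rng.normal(mu * sat, sd))
                reb_on = laser_off + true_rebound
                if is_peak and tr.laser_onset_rel > 0:
                    if rng.random() < stim.p_initiation_given_rebound:
                        pattern = "initiation"
                        # rebound merges into the peak: bout starts at rebound
                        peak_start_override = reb_on
                        if stim.timing_mode in ("pause", "pause_plus_rebound"):
                            pass  # centre unchanged; the peak merely widens
                    else:
                        pattern = "recovery"
                        all_licks += _metronome(rng, reb_on,
                                                reb_on + stim.rebound_bout_duration,
                                                lick.consummatory_frequency,
                                                lick.ili_jitter_sd)
                        if stim.timing_mode in ("pause", "pause_plus_rebound"):
                            true_center += tr.laser_duration + stim.rebound_bout_duration
                else:
                    all_licks += _metronome(rng, reb_on,
                                            reb_on + stim.rebound_bout_duration,
                                            lick.consummatory_frequency,
                                            lick.ili_jitter_sd)
            elif is_peak and tr.laser_onset_rel > 0:
                pattern = "no_rebound"
                if stim.timing_mode in ("pause", "pause_plus_rebound"):
                    true_center += tr.laser_duration

        if is_peak:
            hw = lick.peak_bout_halfwidth
            start = true_center - hw
            if not np.isnan(peak_start_override):
                start = peak_start_override
            all_licks += _metronome(rng, start, true_center + hw,
                                    lick.bout_frequency, lick.ili_jitter_sd)

        truth_rows.append({
            "trial_id": tr.trial_id,
            "kind": tr.kind,
            "laser": has_laser,
            "true_anticipation_onset": ant_onset,
            "true_peak_center": true_center,
            "true_evoke_latency": true_evoke,
            "true_rebound_latency": true_rebound,
            "rebound_pattern": pattern,
            "timing_mode": stim.timing_mode if has_laser else "none",
        })

    ts = np.sort(np.asarray(all_licks, dtype=float))
    ts = ts[ts >= 0]
    for on, off in suppress_windows:
        ts = ts[(ts < on) | (ts > off)]
    train = filter_licks(ts, session_id)

    group = {"d1_evoke": "D1-ChR2", "a2a_suppress": "A2A-ChR2",
             "none": "eYFP-control"}[stim.mode]
    metadata = {"interval": interval, "group": group, "synthetic": True,
                "seed": int(seed), "stim_mode": stim.mode,
                "timing_mode": stim.timing_mode}
    truth = pd.DataFrame(truth_rows)
    return SessionBundle(train, trials, metadata, truth)


def simulate_session(task: TaskParams,
                     lick: Optional[LickModelParams] = None,
                     stim: Optional[StimEffectParams] = None,
                     session_id: str = "synthetic") -> SessionBundle:
    """Scheduler plus licking in one call, seeded from ``task.seed``."""
    trials = simulate_scheduler(task)
    return simulate_licking(trials, lick, stim, seed=task.seed + 1,
                            session_id=session_id, interval=task.interval)


def ground_truth(bundle: SessionBundle) -> pd.DataFrame:
    """Per-trial truth table of a simulated session.

    Columns: true bout (anticipation) onsets, true peak centres, true evoke
    and rebound latencies, rebound pattern, timing mode — one row per trial,
    for parameter-recovery tests.

    Raises
    ------
    ValueError
        If the bundle was not produced by :func:`simulate_licking`.
    """
    if bundle.truth is None or not bundle.metadata.get("synthetic", False):
        raise ValueError("ground truth is only available for synthetic sessions")
    return bundle.truth
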