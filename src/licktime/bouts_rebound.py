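"""Bout onsets, stimulation-effect metrics, rebound classification, and
quartile (motivation) analysis.

A bout onset is the first lick after a gap of >= 1 s (the session's first
lick counts).  Stimulation metrics compare laser trials against matched
no-laser trials of the same kind at the identical trial-relative window:
change in lick rate during stimulation, latency to the first evoked bout
onset, post-offset rebound latency, and post-offset lick counts.  Probe
trials with indirect-pathway stimulation mid-interval are classified by the
temporal pattern of bout onsets around the rebound (recovery / initiation /
no_rebound), and session-half fractions of those labels expose motivational
drift, as does splitting laser trials into ordinal quartiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_events import LickTrain, SessionBundle

#: inter-lick gap that terminates a bout
BOUT_GAP = 1.0

REBOUND_CLASSES = ("recovery", "initiation", "no_rebound")
#: accepted alias: "absorption" names the same pattern as "initiation"
REBOUND_ALIASES = {"absorption": "initiation", "rebound_absorption": "initiation"}


@dataclass(frozen=True)
class BoutOnsets:
    onset_times: np.ndarray

    def first_in(self, start: float, stop: float) -> Optional[float]:
        """Earliest onset in the closed window [start, stop], or None."""
        t = self.onset_times
        hit = t[(t >= start) & (t <= stop)]
        return float(hit[0]) if hit.size else None


def bout_onsets(licks: LickTrain) -> BoutOnsets:
    """Bout onsets: the first lick, then every lick preceded by >= 1 s gap."""
    ts = licks.timestamps
    if ts.size == 0:
        return BoutOnsets(ts.copy())
    is_onset = np.concatenate([[True], np.diff(ts) >= BOUT_GAP])
    return BoutOnsets(ts[is_onset])


# ---------------------------------------------------------------------------
# stimulation-effect metrics


def _matched_baseline_trials(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    base = df[(df["kind"] == kind) & (df["laser_onset_rel"].isna())]
    if base.empty:
        raise ValueError(f"no matched no-laser {kind} trials in session")
    return base


def _baseline_rate(licks: LickTrain, base: pd.DataFrame, rel_start: float,
                   duration: float) -> float:
    counts = [licks.count(r + rel_start, r + rel_start + duration)
              for r in base["reward_time"]]
    return float(np.mean(counts)) / duration


def delta_lick_rate(bundle: SessionBundle) -> tuple[pd.DataFrame, float]:
    """Stimulation-window lick rate minus the matched no-stimulation rate.

    For every laser trial, the raw lick count in the laser window divided by
    its duration, minus the mean rate over the identical trial-relative
    window on no-laser trials of the same kind.  Returns the per-trial table
    and the session (group) mean delta.
    """
    df = bundle.trials.df
    laser = df[df["laser_onset_rel"].notna()]
    if laser.empty:
        raise ValueError("session has no laser trials")
    rows = []
    for kind, sub in laser.groupby("kind"):
        base = _matched_baseline_trials(df, kind)
        rel = float(sub["laser_onset_rel"].iloc[0])
        dur = float(sub["laser_duration"].iloc[0])
        b = _baseline_rate(bundle.licks, base, rel, dur)
        for tr in sub.itertuples(index=False):
            on = tr.reward_time + tr.laser_onset_rel
            rate = bundle.licks.count(on, on + tr.laser_duration) / tr.laser_duration
            rows.append({"trial_id": tr.trial_id, "kind": kind,
                         "stim_rate": rate, "baseline_rate": b,
                         "delta_rate": rate - b})
    table = pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)
    return table, float(table["delta_rate"].mean())


def evoke_latency(onsets: BoutOnsets, laser_on: float,
                  window: float = 1.0) -> float:
    """Latency of the first bout onset during stimulation; NaN if none
    (trials without licking are excluded downstream, not errors)."""
    hit = onsets.first_in(laser_on, laser_on + window)
    return np.nan if hit is None else hit - laser_on


def rebound_latency(onsets: BoutOnsets, laser_off: float,
                    window: float = 3.0) -> float:
    """Latency of the first bout onset in [0, window] s after laser offset;
    NaN if none.  The same window applies to matched no-laser trials."""
    hit = onsets.first_in(laser_off, laser_off + window)
    return np.nan if hit is None else hit - laser_off


def latency_summary(latencies: Sequence[float]) -> dict:
    """Mean and unbiased (n-1) variance of non-missing latencies."""
    lat = np.asarray(latencies, dtype=float)
    lat = lat[~np.isnan(lat)]
    return {
        "n": int(lat.size),
        "mean": float(lat.mean()) if lat.size else np.nan,
        "variance": float(lat.var(ddof=1)) if lat.size > 1 else np.nan,
    }


def post_offset_count(licks: LickTrain, laser_off: float,
                      window: float = 1.0) -> int:
    """Lick count in the 1 s following stimulation offset."""
    return licks.count(laser_off, laser_off + window)


def stim_trial_metrics(bundle: SessionBundle) -> pd.DataFrame:
    """Per-laser-trial stimulation metrics with quartile assignment.

    Columns: delta_rate, evoke_latency, rebound_latency (both NaN when no
    onset fell in the window), post_offset_count and its no-laser baseline,
    and the ordinal quartile (1-4) by laser-presentation order.
    """
    delta, _ = delta_lick_rate(bundle)
    onsets = bout_onsets(bundle.licks)
    df = bundle.trials.df
    laser = df[df["laser_onset_rel"].notna()]
    rows = []
    for tr in laser.itertuples(index=False):
        on = tr.reward_time + tr.laser_onset_rel
        off = on + tr.laser_duration
        base = _matched_baseline_trials(df, tr.kind)
        rel_off = tr.laser_onset_rel + tr.laser_duration
        base_count = float(np.mean(
            [bundle.licks.count(r + rel_off, r + rel_off + 1.0)
             for r in base["reward_time"]]))
        rows.append({
            "trial_id": tr.trial_id,
            "evoke_latency": evoke_latency(onsets, on, tr.laser_duration),
            "rebound_latency": rebound_latency(onsets, off),
            "post_offset_count": post_offset_count(bundle.licks, off),
            "baseline_post_offset_count": base_count,
        })
    out = pd.DataFrame(rows)
    out = out.merge(delta[["trial_id", "delta_rate"]], on="trial_id")
    out = out.sort_values("trial_id").reset_index(drop=True)
    out["quartile"] = _ordinal_quartiles(len(out))
    return out


def _ordinal_quartiles(n: int) -> np.ndarray:
    q = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(np.arange(n), 4)):
        q[chunk] = i + 1
    return q


def quartile_analysis(bundle: SessionBundle, metric: str) -> pd.DataFrame:
    """Mean of a stimulation metric per ordinal quartile of laser trials.

    Runs on the full session (never the first-half selection) and requires
    at least 4 laser trials.  ``metric`` is a column of
    :func:`stim_trial_metrics`; missing values are skipped within quartiles.
    """
    table = stim_trial_metrics(bundle)
    if len(table) < 4:
        raise ValueError("quartile analysis requires at least 4 laser trials")
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    g = table.groupby("quartile")[metric]
    out = g.agg(mean="mean", n="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# rebound classification


def classify_rebound_trial(licks: LickTrain, trial,
                           rebound_window: float = 2.0,
                           second_onset_window: float = 8.0) -> str:
    """Classify a probe trial with mid-interval indirect-pathway stimulation.

    A bout onset within the closed [0, 2] s window after stimulation onset
    marks a rebound; a second onset within the half-open (0, 8] s window
    after the rebound onset makes the trial a ``recovery`` (rebound then a
    separate peak bout), otherwise the rebound absorbed the peak
    (``initiation``).  With no onset after stimulation onset the trial is
    ``no_rebound``.
    """
    if trial.kind != "peak":
        raise ValueError("rebound classification applies to peak probe trials")
    if np.isnan(trial.laser_onset_rel) or trial.laser_onset_rel <= 0:
        raise ValueError("rebound classification requires mid-interval laser "
                         "(onset after the initiating reward)")
    stim_on = trial.reward_time + trial.laser_onset_rel
    onsets = bout_onsets(licks)
    reb = onsets.first_in(stim_on, stim_on + rebound_window)
    if reb is None:
        return "no_rebound"
    t = onsets.onset_times
    second = t[(t > reb) & (t <= reb + second_onset_window)]
    return "recovery" if second.size else "initiation"


def canonical_rebound_label(label: str) -> str:
    """Map accepted aliases (e.g. "absorption") onto the canonical label."""
    label = REBOUND_ALIASES.get(label, label)
    if label not in REBOUND_CLASSES:
        raise ValueError(f"unknown rebound class {label!r}")
    return label


def classify_session(bundle: SessionBundle) -> pd.DataFrame:
    """Rebound class for every eligible probe trial (laser after reward)."""
    df = bundle.trials.df
    eligible = df[(df["kind"] == "peak") & (df["laser_onset_rel"] > 0)]
    rows = [{"trial_id": tr.trial_id,
             "label": classify_rebound_trial(bundle.licks, tr)}
            for tr in eligible.itertuples(index=False)]
    return pd.DataFrame(rows, columns=["trial_id", "label"])


def rebound_session_half_fractions(labels: Sequence[str]) -> pd.DataFrame:
    """Fraction of each rebound class in the first and second session half.

    Labels must be in presentation order; halves split at ceil(n/2) and each
    must contain at least 2 classified trials.  Fractions sum to 1 per half.
    """
    labels = [canonical_rebound_label(l) for l in labels]
    n = len(labels)
    cut = math.ceil(n / 2)
    halves = {1: labels[:cut], 2: labels[cut:]}
    for h, ls in halves.items():
        if len(ls) < 2:
            raise ValueError(f"session half {h} has fewer than 2 classified trials")
    rows = []
    for h, ls in halves.items():
        for cls in REBOUND_CLASSES:
            rows.append({"half": h, "label": cls,
                         "fraction": ls.count(cls) / len(ls)})
    return pd.DataFrame(rows)
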