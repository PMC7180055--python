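"""Canonical data model for lick/event streams and session I/O.

A *session* is one head-fixed recording: a train of lick contact times, a
table of trials (reward deliveries, optional laser stimulation, optional
unrewarded peak-probe trials), and free-form metadata.  All times are float
seconds on a single session clock starting at 0; trial-relative times are
computed on demand, never stored.

The on-disk format is a directory holding

* ``events.csv`` — tidy event stream with columns ``time_s`` (float),
  ``event`` in {lick, reward, laser_on, laser_off}, ``trial_id`` (int);
* ``session.yaml`` — metadata plus the per-trial fields that cannot be
  recovered from the event stream (trial kind, probe duration, laser
  frequency);
* ``ground_truth.csv`` — present only for simulated sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

#: Minimum credible inter-lick interval.  Contact events closer than this are
#: lickometer chatter, not tongue protrusions, and are removed on ingest.
MIN_ILI = 0.008

EVENT_CODES = ("lick", "reward", "laser_on", "laser_off")

TRIAL_COLUMNS = [
    "trial_id",
    "reward_time",
    "kind",
    "laser_onset_rel",
    "laser_duration",
    "laser_frequency",
    "probe_duration",
]


class MalformedInputError(ValueError):
    """Raised for non-finite or inconsistent raw event input."""


class SessionFormatError(ValueError):
    """Raised when a session file violates the events-CSV dialect."""


@dataclass(frozen=True)
class LickTrain:
    """Ordered lick contact times for one session.

    Parameters
    ----------
    timestamps :
        Strictly increasing times in seconds from session start.  After
        :func:`filter_licks` every consecutive gap is >= ``MIN_ILI``.
    session_id :
        Free-form identifier, carried through analyses.
    """

    timestamps: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise MalformedInputError("lick timestamps must be 1-D")
        if ts.size and not np.all(np.isfinite(ts)):
            raise MalformedInputError("non-finite lick timestamp")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise MalformedInputError("lick timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def in_window(self, start: float, stop: float) -> np.ndarray:
        """Licks ``t`` with ``start <= t <= stop`` (closed window)."""
        ts = self.timestamps
        return ts[(ts >= start) & (ts <= stop)]

    def count(self, start: float, stop: float) -> int:
        return int(self.in_window(start, stop).size)

    def shifted(self, delta: float) -> "LickTrain":
        return LickTrain(self.timestamps + delta, self.session_id)


@dataclass
class TrialTable:
    """Per-trial task structure: reward time, kind, laser, probe duration.

    Wraps a :class:`pandas.DataFrame` with columns ``TRIAL_COLUMNS``.
    ``kind`` is ``"fixed"`` (rewarded fixed-time trial) or ``"peak"``
    (unrewarded probe; ``reward_time`` is then the *initiating* reward and
    ``probe_duration`` the unrewarded stretch that follows it).  Laser fields
    are NaN on no-stimulation trials; ``laser_onset_rel`` is seconds relative
    to ``reward_time`` (negative = before reward).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise SessionFormatError(f"trial table missing columns {missing}")
        df = df[TRIAL_COLUMNS].reset_index(drop=True)
        df["trial_id"] = df["trial_id"].astype(int)
        if df["trial_id"].duplicated().any():
            dup = int(df.loc[df["trial_id"].duplicated(), "trial_id"].iloc[0])
            raise SessionFormatError(f"duplicate trial_id {dup}")
        if not df["reward_time"].is_monotonic_increasing:
            raise SessionFormatError("trials must be ordered by reward_time")
        bad_kind = ~df["kind"].isin(["fixed", "peak"])
        if bad_kind.any():
            raise SessionFormatError(
                f"unknown trial kind {df.loc[bad_kind, 'kind'].iloc[0]!r}"
            )
        peak = df["kind"] == "peak"
        if (df.loc[peak, "probe_duration"] < 30.0).any():
            raise SessionFormatError("peak trials require probe_duration >= 30 s")
        has_laser = df["laser_onset_rel"].notna()
        if (df.loc[has_laser, "laser_duration"] <= 0).any():
            raise SessionFormatError("laser_duration must be > 0 when laser present")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def itertrials(self):
        return self.df.itertuples(index=False)

    @property
    def laser_mask(self) -> np.ndarray:
        return self.df["laser_onset_rel"].notna().to_numpy()

    def laser_on_times(self) -> np.ndarray:
        """Absolute laser-onset times for trials with stimulation."""
        d = self.df[self.df["laser_onset_rel"].notna()]
        return (d["reward_time"] + d["laser_onset_rel"]).to_numpy()

    def subset(self, mask) -> "TrialTable":
        return TrialTable(self.df.loc[mask].reset_index(drop=True))


@dataclass
class SessionBundle:
    """One session: licks, trials, metadata, optional generator ground truth."""

    licks: LickTrain
    trials: TrialTable
    metadata: dict = field(default_factory=dict)
    truth: Optional[pd.DataFrame] = None

    @property
    def interval(self) -> float:
        """Trained fixed-time interval in seconds (default 10)."""
        return float(self.metadata.get("interval", 10.0))


def filter_licks(raw_timestamps: Iterable[float], session_id: str = "") -> LickTrain:
    """Debounce a raw contact-time sequence with the minimum-ILI rule.

    A lick is retained iff its gap from the previously *retained* lick is at
    least ``MIN_ILI`` (greedy scan; the first lick is always retained).  The
    scan is idempotent: filtering a filtered train changes nothing.

    Raises
    ------
    MalformedInputError
        If any timestamp is non-finite.
    """
    ts = np.asarray(list(raw_timestamps) if not isinstance(raw_timestamps, np.ndarray)
                    else raw_timestamps, dtype=float)
    if ts.size and not np.all(np.isfinite(ts)):
        raise MalformedInputError("non-finite timestamp in raw lick input")
    ts = np.sort(ts)
    if ts.size == 0:
        return LickTrain(ts, session_id)
    kept = [ts[0]]
    last = ts[0]
    for t in ts[1:]:
        if t - last >= MIN_ILI:
            kept.append(t)
            last = t
    return LickTrain(np.asarray(kept), session_id)


def select_first_half(bundle: SessionBundle) -> SessionBundle:
    """Restrict a session to its first half of trials.

    Motivational state drifts within a session, so unless an analysis says
    otherwise it runs on trials ``1..ceil(N/2)`` and the licks within their
    span.  The cut time is the end of the last retained trial (initiating
    reward + probe duration for peak trials, + one fixed interval otherwise),
    clipped at the next trial's reward.
    """
    n = len(bundle.trials)
    if n < 2:
        raise ValueError("need at least 2 trials to split a session")
    keep = math.ceil(n / 2)
    df = bundle.trials.df
    last = df.iloc[keep - 1]
    if last["kind"] == "peak":
        cut = last["reward_time"] + last["probe_duration"]
    else:
        cut = last["reward_time"] + bundle.interval
    if keep < n:
        cut = min(cut, float(df["reward_time"].iloc[keep]))
    licks = LickTrain(bundle.licks.timestamps[bundle.licks.timestamps <= cut],
                      bundle.licks.session_id)
    trials = TrialTable(df.iloc[:keep])
    truth = None
    if bundle.truth is not None:
        truth = bundle.truth[bundle.truth["trial_id"].isin(trials.df["trial_id"])]
        truth = truth.reset_index(drop=True)
    return SessionBundle(licks, trials, dict(bundle.metadata), truth)


# ---------------------------------------------------------------------------
# session directory I/O


def write_session(bundle: SessionBundle, path) -> None:
    """Write a session directory (events.csv + session.yaml [+ ground_truth])."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    df = bundle.trials.df
    reward_times = df["reward_time"].to_numpy()
    trial_ids = df["trial_id"].to_numpy()
    # a lick is attributed to the trial whose reward it anticipates
    idx = np.searchsorted(reward_times, bundle.licks.timestamps, side="left")
    idx = np.minimum(idx, len(df) - 1)
    for t, i in zip(bundle.licks.timestamps, idx):
        rows.append((t, "lick", int(trial_ids[i])))
    for tr in bundle.trials.itertrials():
        rows.append((tr.reward_time, "reward", int(tr.trial_id)))
        if not np.isnan(tr.laser_onset_rel):
            on = tr.reward_time + tr.laser_onset_rel
            rows.append((on, "laser_on", int(tr.trial_id)))
            rows.append((on + tr.laser_duration, "laser_off", int(tr.trial_id)))
    events = pd.DataFrame(rows, columns=["time_s", "event", "trial_id"])
    events = events.sort_values(["time_s", "event"], kind="stable").reset_index(drop=True)
    # %.17g round-trips IEEE doubles exactly
    events.to_csv(path / "events.csv", index=False, float_format="%.17g")

    sidecar = {
        "session_id": bundle.licks.session_id,
        "metadata": _plain(bundle.metadata),
        "trials": [
            {
                "trial_id": int(tr.trial_id),
                "kind": str(tr.kind),
                "probe_duration": _plain(tr.probe_duration),
                "laser_frequency": _plain(tr.laser_frequency),
            }
            for tr in bundle.trials.itertrials()
        ],
    }
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    if bundle.truth is not None:
        bundle.truth.to_csv(path / "ground_truth.csv", index=False,
                            float_format="%.17g")


def read_session(path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`.

    ``read_session(write_session(b)) == b`` field-for-field; lick times are
    written at full precision so the round trip is exact.
    """
    path = Path(path)
    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    for col in ("time_s", "event", "trial_id"):
        if col not in events.columns:
            raise SessionFormatError(f"events.csv missing required column {col!r}")
    bad = ~events["event"].isin(EVENT_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SessionFormatError(
            f"unknown event code {events['event'].iloc[row]!r} at events.csv row {row}"
        )
    with open(path / "session.yaml") as fh:
        sidecar = yaml.safe_load(fh)

    rewards = events[events["event"] == "reward"]
    if rewards["trial_id"].duplicated().any():
        dup = int(rewards.loc[rewards["trial_id"].duplicated(), "trial_id"].iloc[0])
        raise SessionFormatError(f"duplicate trial_id {dup} among reward events")
    reward_by_id = dict(zip(rewards["trial_id"].astype(int), rewards["time_s"]))

    on = events[events["event"] == "laser_on"].set_index("trial_id")["time_s"]
    off = events[events["event"] == "laser_off"].set_index("trial_id")["time_s"]

    trial_rows = []
    for tr in sidecar.get("trials", []):
        tid = int(tr["trial_id"])
        if tid not in reward_by_id:
            raise SessionFormatError(f"trial {tid} listed in session.yaml has no reward event")
        rt = float(reward_by_id[tid])
        onset_rel = duration = np.nan
        if tid in on.index:
            onset_rel = float(on.loc[tid]) - rt
            if tid not in off.index:
                raise SessionFormatError(f"trial {tid} has laser_on but no laser_off")
            duration = float(off.loc[tid]) - float(on.loc[tid])
        trial_rows.append(
            {
                "trial_id": tid,
                "reward_time": rt,
                "kind": tr["kind"],
                "laser_onset_rel": onset_rel,
                "laser_duration": duration,
                "laser_frequency": _nanfloat(tr.get("laser_frequency")),
                "probe_duration": _nanfloat(tr.get("probe_duration")),
            }
        )
    trials = TrialTable(pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS))

    lick_ts = events.loc[events["event"] == "lick", "time_s"].to_numpy(dtype=float)
    licks = LickTrain(np.sort(lick_ts), str(sidecar.get("session_id", "")))

    truth = None
    truth_path = path / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, float_precision="round_trip")
    return SessionBundle(licks, trials, dict(sidecar.get("metadata") or {}), truth)


def _plain(x):
    """YAML-safe scalar/dict conversion (numpy scalars, NaN -> None)."""
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (np.floating, float)):
        return None if np.isnan(x) else float(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _nanfloat(x) -> float:
    return np.nan if x is None else float(x)
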