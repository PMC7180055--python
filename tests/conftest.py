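"""Shared fixtures: programmatically built trial tables and sessions."""

import numpy as np
import pandas as pd
import pytest

from licktime.io_events import TRIAL_COLUMNS, TrialTable


def make_probe_table(n_trials: int, laser_onset=None, laser_every: int = 1,
                     probe_duration: float = 40.0, laser_frequency: float = 25.0,
                     start: float = 10.0) -> TrialTable:
    """Table of peak-probe trials; every ``laser_every``-th gets the laser."""
    rows = []
    t = start
    for i in range(n_trials):
        laser = laser_onset is not None and i % laser_every == 0
        rows.append({
            "trial_id": i,
            "reward_time": t,
            "kind": "peak",
            "laser_onset_rel": laser_onset if laser else np.nan,
            "laser_duration": 1.0 if laser else np.nan,
            "laser_frequency": laser_frequency if laser else np.nan,
            "probe_duration": probe_duration,
        })
        t += probe_duration
    return TrialTable(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def make_fixed_table(n_trials: int, laser_onset=None, laser_every: int = 2,
                     interval: float = 10.0, laser_frequency: float = 10.0,
                     start: float = 10.0) -> TrialTable:
    """Table of fixed-time trials; every ``laser_every``-th gets the laser."""
    rows = []
    t = start
    for i in range(n_trials):
        laser = laser_onset is not None and i % laser_every == 0
        rows.append({
            "trial_id": i,
            "reward_time": t,
            "kind": "fixed",
            "laser_onset_rel": laser_onset if laser else np.nan,
            "laser_duration": 1.0 if laser else np.nan,
            "laser_frequency": laser_frequency if laser else np.nan,
            "probe_duration": np.nan,
        })
        t += interval
    return TrialTable(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def metronome(start, stop, freq, jitter_sd=0.0, rng=None):
    """Reference jittered-metronome bout used to build oracle lick trains."""
    out = []
    t = start
    while t < stop:
        out.append(t)
        ili = 1.0 / freq
        if jitter_sd and rng is not None:
            ili += rng.normal(0.0, jitter_sd)
        t += max(ili, 0.05)
    return out


@pytest.fixture
def probe_table_20():
    return make_probe_table(20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
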