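"""Trial-table builder shared by the acceptance script's scenarios."""

import numpy as np
import pandas as pd

from licktime.io_events import TRIAL_COLUMNS, TrialTable


def probe_table(n_trials: int, laser_onset=None, probe_duration: float = 40.0,
                laser_frequency: float = 25.0, start: float = 10.0) -> TrialTable:
    rows = []
    t = start
    for i in range(n_trials):
        laser = laser_onset is not None
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
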