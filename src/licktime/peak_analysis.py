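"""Single-trial peak detection on probe trials and peak statistics.

On an unrewarded probe trial the animal emits a discrete bout of anticipatory
licking whose centre estimates its internal representation of the trained
interval.  Detection follows a change-point recipe: the smoothed lick-rate
trace in a 20-s window after the initiating reward is segmented by a
change-in-mean fit; the first rising change point and the next falling one
delimit the candidate peak, which is fit with a Gaussian whose mean is the
single-trial peak time.  A candidate must last >= 2 s and exceed 3 Hz; on
failure the window slides right by 0.5 s, up to 5 times, before the trial is
discarded.  For stimulation trials the initial window is shifted right to
keep stimulation-evoked or rebound licking from being scored as the peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_events import LickTrain, SessionBundle
from .rate_spectral import DEFAULT_BIN_WIDTH, DEFAULT_SMOOTHING_SD, rate_trace


class FitError(RuntimeError):
    """Gaussian fit failed to converge (or had nothing to fit)."""


@dataclass(frozen=True)
class Peak:
    """A detected single-trial peak (times in trial-relative seconds)."""

    trial_id: int
    start: float
    end: float
    peak_time: float      # Gaussian fit mean
    amplitude: float      # Hz
    sigma: float          # s
    n_window_shifts_used: int
    valid: bool = True


@dataclass
class PeakConfig:
    """Tunable knobs of the peak-detection recipe (defaults per the task)."""

    window_len: float = 20.0
    bin_width: float = DEFAULT_BIN_WIDTH
    smoothing_sd: float = DEFAULT_SMOOTHING_SD
    shift_step: float = 0.5
    max_shifts: int = 5
    min_duration: float = 2.0      # s
    min_rate: float = 3.0          # Hz, on the smoothed trace's maximum
    penalty: Optional[float] = None
    max_changepoints: int = 8
    slope_halfwidth: int = 5       # bins, for rising/falling classification


@dataclass
class PeakSessionStats:
    mean_peak_time: float
    peak_shift: float              # s, laser minus no-laser (NaN if no baseline)
    mean_width: float
    skewness: float
    n_trials_used: int
    n_discarded: int


# ---------------------------------------------------------------------------
# change-in-mean segmentation


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """C[i, j] = within-segment sum of squares of x[i:j] (L2 cost)."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    length = j - i
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (ss[None, :] - ss[:, None]) - (s[None, :] - s[:, None]) ** 2 / length
    c[length <= 0] = np.inf
    np.fill_diagonal(c, 0.0)
    return c


def changepoints_mean(sig, penalty: Optional[float] = None,
                      max_changepoints: int = 8,
                      slope_halfwidth: int = 5) -> list:
    """Penalized change-in-mean segmentation of a rate signal.

    Finds the segmentation minimizing (residual sum of squares +
    penalty * n_changepoints) by exact dynamic programming over at most
    ``max_changepoints`` changepoints.  The default penalty,
    ``2 * log(n) * var(signal)``, targets the coarse transitions of a
    smoothed trace rather than bin noise.  Each changepoint is classified as
    rising or falling by the mean of ``slope_halfwidth`` bins after it minus
    the mean of the same number before (clipped at the edges); zero
    differences are dropped.

    Returns a list of ``(index, "rising" | "falling")`` where ``index`` is
    the first bin of the new segment.  A constant signal yields ``[]``.
    """
    x = np.asarray(sig, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("changepoint detection needs at least 10 bins")
    var = float(np.var(x))
    if var == 0.0:
        return []
    if penalty is None:
        penalty = 2.0 * math.log(n) * var

    cost = _segment_costs(x)
    kmax = min(max_changepoints, n - 1)
    # D[k, j]: best cost of x[:j] with exactly k changepoints
    D = np.full((kmax + 1, n + 1), np.inf)
    D[0] = cost[0]
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    for k in range(1, kmax + 1):
        # candidate previous boundary i: D[k-1, i] + cost[i, j]
        m = D[k - 1][:, None] + cost
        back[k] = np.argmin(m, axis=0)
        D[k] = m[back[k], np.arange(n + 1)]
    totals = D[:, n] + penalty * np.arange(kmax + 1)
    k_star = int(np.argmin(totals))        # ties resolve to fewer changepoints

    bps = []
    j = n
    for k in range(k_star, 0, -1):
        j = int(back[k, j])
        bps.append(j)
    bps = sorted(bps)

    out = []
    for i in bps:
        lo = max(0, i - slope_halfwidth)
        hi = min(n, i + slope_halfwidth)
        diff = x[i:hi].mean() - x[lo:i].mean()
        if diff > 0:
            out.append((i, "rising"))
        elif diff < 0:
            out.append((i, "falling"))
    return out


# ---------------------------------------------------------------------------
# Gaussian peak fit


def _gauss(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(t: np.ndarray, y: np.ndarray):
    """Least-squares Gaussian fit to a rate segment.

    Initialized at (max, argmax, span/4); the mean is bounded to the
    segment and sigma to [0.1, 10] s.  Returns ``(amplitude, mean, sigma)``.

    Raises
    ------
    FitError
        For segments shorter than 5 bins, all-zero segments, or a
        non-converging fit.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise FitError("segment too short to fit (need >= 5 bins)")
    if np.max(y) <= 0:
        raise FitError("segment carries no rate to fit")
    span = t[-1] - t[0]
    p0 = (float(np.max(y)), float(t[np.argmax(y)]), max(span / 4.0, 0.1))
    bounds = ([1e-9, t[0], 0.1], [np.inf, t[-1], 10.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(_gauss, t, y, p0=p0, bounds=bounds,
                                         maxfev=2000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"gaussian fit did not converge: {exc}") from None
    return float(popt[0]), float(popt[1]), float(popt[2])


# ---------------------------------------------------------------------------
# single-trial detection


def detect_peak(licks: LickTrain, reward_time: float,
                window_start: float = 0.0,
                config: Optional[PeakConfig] = None,
                trial_id: int = -1) -> Optional[Peak]:
    """Detect the single-trial peak on a probe trial.

    ``window_start`` is the left edge of the initial 20-s analysis window in
    seconds after the initiating reward; it is 0 by default, equal to the
    stimulation delay for direct-pathway trials stimulated at +3/+5 s, and
    6 s for rebound-recovery trials (see :func:`window_start_for_trial`).
    Returns ``None`` when no valid peak is found after all window shifts.
    """
    cfg = config or PeakConfig()
    for attempt in range(cfg.max_shifts + 1):
        ws = window_start + attempt * cfg.shift_step
        trace = rate_trace(licks, reward_time, (ws, ws + cfg.window_len),
                           bin_width=cfg.bin_width, smoothing_sd=cfg.smoothing_sd)
        cps = changepoints_mean(trace.rate, penalty=cfg.penalty,
                                max_changepoints=cfg.max_changepoints,
                                slope_halfwidth=cfg.slope_halfwidth)
        seg = _first_rise_fall(cps)
        if seg is None:
            continue
        i_rise, i_fall = seg
        start = ws + i_rise * cfg.bin_width
        end = ws + i_fall * cfg.bin_width
        seg_rate = trace.rate[i_rise:i_fall]
        if end - start < cfg.min_duration or seg_rate.max() <= cfg.min_rate:
            continue
        try:
            amp, mu, sigma = fit_gaussian(trace.bin_centers[i_rise:i_fall], seg_rate)
        except FitError:
            continue
        return Peak(trial_id, start, end, mu, amp, sigma,
                    n_window_shifts_used=attempt, valid=True)
    return None


def _first_rise_fall(cps) -> Optional[tuple]:
    """First rising changepoint and the next falling one after it."""
    rise = next((i for i, d in cps if d == "rising"), None)
    if rise is None:
        return None
    fall = next((i for i, d in cps if d == "falling" and i > rise), None)
    if fall is None:
        return None
    return rise, fall


def window_start_for_trial(trial, stim_mode: str,
                           rebound_label: Optional[str] = None) -> float:
    """Initial analysis-window left edge for one probe trial.

    No-stimulation probes start at the reward (0 s).  Direct-pathway trials
    stimulated after the reward shift right by the stimulation delay so
    evoked licking is not scored as the peak; rebound-recovery trials after
    indirect-pathway stimulation shift by 6 s to exclude the rebound bout.
    """
    onset = trial.laser_onset_rel
    if onset is None or (isinstance(onset, float) and np.isnan(onset)) or onset <= 0:
        return 0.0
    if stim_mode == "d1_evoke":
        return float(onset)
    if stim_mode == "a2a_suppress" and rebound_label == "recovery":
        return 6.0
    return 0.0


def detect_session_peaks(bundle: SessionBundle,
                         config: Optional[PeakConfig] = None,
                         rebound_labels: Optional[dict] = None) -> dict:
    """Run :func:`detect_peak` on every probe trial of a session.

    Returns ``{trial_id: Peak | None}``.  ``rebound_labels`` maps trial_id to
    a rebound class for window placement on indirect-pathway sessions.
    """
    stim_mode = bundle.metadata.get("stim_mode", "none")
    labels = rebound_labels or {}
    out = {}
    for tr in bundle.trials.itertrials():
        if tr.kind != "peak":
            continue
        ws = window_start_for_trial(tr, stim_mode, labels.get(tr.trial_id))
        out[tr.trial_id] = detect_peak(bundle.licks, tr.reward_time,
                                       window_start=ws, config=config,
                                       trial_id=tr.trial_id)
    return out


# ---------------------------------------------------------------------------
# session-level statistics


def peak_stats(peaks: Iterable[Optional[Peak]], licks: LickTrain,
               reward_times: dict,
               baseline_peaks: Optional[Iterable[Peak]] = None) -> PeakSessionStats:
    """Session-level peak statistics over detected peaks.

    Width is end minus start per trial; skewness is the third standardized
    moment of the pooled trial-relative lick times falling inside each
    trial's peak; ``peak_shift`` is the mean peak time minus the mean over
    ``baseline_peaks`` (the same session's no-laser probes) when given.
    """
    valid = [p for p in peaks if p is not None and p.valid]
    n_discarded = sum(1 for p in peaks if p is None or not p.valid) \
        if isinstance(peaks, (list, tuple)) else 0
    if not valid:
        raise ValueError("no valid peaks to summarize")
    pooled = []
    for p in valid:
        r = reward_times[p.trial_id]
        pooled.append(licks.in_window(r + p.start, r + p.end) - r)
    pooled = np.concatenate(pooled) if pooled else np.array([])
    skew = float(stats.skew(pooled)) if pooled.size >= 3 else np.nan
    mean_time = float(np.mean([p.peak_time for p in valid]))
    shift = np.nan
    if baseline_peaks is not None:
        base = [p.peak_time for p in baseline_peaks if p is not None and p.valid]
        if base:
            shift = mean_time - float(np.mean(base))
    return PeakSessionStats(
        mean_peak_time=mean_time,
        peak_shift=shift,
        mean_width=float(np.mean([p.end - p.start for p in valid])),
        skewness=skew,
        n_trials_used=len(valid),
        n_discarded=n_discarded,
    )


def peak_shift_curve(bundles: Sequence[SessionBundle],
                     config: Optional[PeakConfig] = None) -> pd.DataFrame:
    """Peak shift as a function of stimulation onset across sessions.

    Each session contributes one row: stimulation onset (s after reward),
    mean laser-probe peak time minus mean no-laser-probe peak time, and the
    trial counts behind both means.  The full session is used (not the
    first-half default) to maximize the number of probes per condition.
    Sessions in which either condition yields no valid peak are omitted with
    a warning.
    """
    rows = []
    for bundle in bundles:
        df = bundle.trials.df
        probes = df[df["kind"] == "peak"]
        laser = probes[probes["laser_onset_rel"].notna()]
        if laser.empty:
            warnings.warn("session without laser probe trials; omitted")
            continue
        onset = float(laser["laser_onset_rel"].iloc[0])
        peaks = detect_session_peaks(bundle, config=config)
        las = [peaks[t] for t in laser["trial_id"] if peaks.get(t)]
        base_ids = probes.loc[probes["laser_onset_rel"].isna(), "trial_id"]
        base = [peaks[t] for t in base_ids if peaks.get(t)]
        if not las or not base:
            warnings.warn(f"no valid peaks for stim onset {onset}; omitted")
            continue
        shift = float(np.mean([p.peak_time for p in las])
                      - np.mean([p.peak_time for p in base]))
        rows.append({"stim_onset": onset, "peak_shift": shift,
                     "n_laser": len(las), "n_baseline": len(base)})
    return pd.DataFrame(rows, columns=["stim_onset", "peak_shift",
                                       "n_laser", "n_baseline"])
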