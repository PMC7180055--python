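"""Leaky-integrator / central-pattern-generator model of lick control.

Basal-ganglia output is modelled as a leaky integrator filled impulsively by
direct-pathway input pulses and discharged by indirect-pathway pulses:

    dI/dt = -leak_rate * I,   I += fill_gain per D1 pulse,
                              I -= discharge_gain per A2A pulse,  I >= 0.

The integrator level gates a discrete-mode lick pattern generator through
three thresholds theta1 < theta2 < theta3 mapping to off / low / mid / high
licking modes (default 5, 7, 9.5 Hz), with emitted inter-lick intervals hard-
capped at 1/cap (10 Hz).  Sustained indirect-pathway drive charges a
hyperpolarization variable; when stimulation ends the charge is released
through a low-pass stage whose rising drive produces a transient
suprathreshold burst — rebound licking — with onset latency decreasing, and
tightening, as the accumulated charge grows.

The decay between pulses is integrated exactly (exponential update), so the
free-decay phase matches the closed-form solution to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from ._errors import ConfigError

_E = math.e
#: an A2A pulse within this window counts as ongoing inhibition, clamping
#: the rebound release stage at zero until stimulation ends
A2A_CLAMP_WINDOW = 0.25


@dataclass
class IntegratorParams:
    """All constants of the integrator-CPG model (dimensionless level units)."""

    fill_gain: float = 1.0         # level per D1 pulse
    discharge_gain: float = 1.0    # level per A2A pulse
    leak_rate: float = 1.0         # 1/s
    thresholds: tuple = (1.5, 2.2, 8.0)
    mode_frequencies: tuple = (5.0, 7.0, 9.5)   # Hz for modes 1..3
    cap: float = 10.0              # Hz, hard limit of the pattern generator
    rebound_gain: float = 0.6      # hyperpolarization charge per A2A pulse
    rebound_decay: float = 1.0     # 1/s, release time constant
    dt: float = 0.001              # s

    def validate(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (t1 < t2 < t3):
            raise ConfigError("thresholds must satisfy theta1 < theta2 < theta3")
        if any(f > self.cap for f in self.mode_frequencies):
            raise ConfigError("mode frequencies must not exceed the cap")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.dt > 0.01:
            raise ConfigError("dt too coarse (> 0.01 s) for threshold crossings")
        if self.leak_rate <= 0 or self.rebound_decay <= 0:
            raise ConfigError("leak_rate and rebound_decay must be positive")


@dataclass
class SimulationResult:
    time: np.ndarray
    level: np.ndarray          # integrator I
    hyper: np.ndarray          # hyperpolarization charge H
    rebound_drive: np.ndarray  # released drive R (adds to I for gating)
    mode: np.ndarray           # 0 = off, 1..3 = discrete CPG modes
    lick_times: np.ndarray


@njit(cache=True)
def _core(d1_imp, a2a_imp, a2a_recent, dt, fill, discharge, leak_factor,
          th1, th2, th3, f1, f2, f3, cap, reb_gain, reb_decay, i0):
    n = d1_imp.shape[0]
    level = np.empty(n)
    hyper = np.empty(n)
    rdrive = np.empty(n)
    mode = np.zeros(n, dtype=np.int8)
    licks = np.empty(n)
    n_licks = 0
    I = i0
    H = 0.0
    R = 0.0
    prev_mode = 0
    next_lick = -1.0
    last_lick = -1e18
    min_ili = 1.0 / cap
    for s in range(n):
        t = s * dt
        I += d1_imp[s] * fill - a2a_imp[s] * discharge
        if I < 0.0:
            I = 0.0
        H += a2a_imp[s] * reb_gain
        if a2a_recent[s]:
            R = 0.0
        else:
            R += dt * reb_decay * (_E * H - R)
            H -= dt * reb_decay * H
        L = I + R
        if L >= th3:
            m = 3
        elif L >= th2:
            m = 2
        elif L >= th1:
            m = 1
        else:
            m = 0
        freq = f1 if m == 1 else (f2 if m == 2 else f3)
        if m != prev_mode:
            if m == 0:
                next_lick = -1.0
            elif prev_mode == 0:
                next_lick = t               # re-phase: immediate first lick
            else:
                # period switch keeps phase anchored at the last lick
                next_lick = last_lick + 1.0 / freq
        if m > 0 and next_lick >= 0.0 and t >= next_lick:
            if t - last_lick >= min_ili - 1e-12:
                licks[n_licks] = t
                n_licks += 1
                last_lick = t
                next_lick = t + 1.0 / freq
            else:
                next_lick = last_lick + min_ili
        level[s] = I
        hyper[s] = H
        rdrive[s] = R
        mode[s] = m
        prev_mode = m
        I *= leak_factor   # exact exponential decay over dt
    return level, hyper, rdrive, mode, licks[:n_licks]


def pulse_train(frequency: float, duration: float, start: float = 0.0) -> np.ndarray:
    """Regular stimulation pulse times, ``frequency`` Hz for ``duration`` s."""
    return start + np.arange(0.0, duration, 1.0 / frequency)


def simulate(d1_pulses: Sequence[float] = (), a2a_pulses: Sequence[float] = (),
             params: Optional[IntegratorParams] = None,
             t_end: Optional[float] = None,
             initial_level: float = 0.0) -> SimulationResult:
    """Integrate the model over given D1 / A2A pulse trains.

    ``t_end`` defaults to 3 s past the last pulse.  ``initial_level``
    pre-charges the integrator, which is convenient for studying the pure
    decay phase.
    """
    p = params or IntegratorParams()
    p.validate()
    d1 = np.asarray(d1_pulses, dtype=float)
    a2a = np.asarray(a2a_pulses, dtype=float)
    last = max(d1.max() if d1.size else 0.0, a2a.max() if a2a.size else 0.0)
    if t_end is None:
        t_end = last + 3.0
    if (d1.size and d1.max() > t_end) or (a2a.size and a2a.max() > t_end):
        raise ConfigError("protocol pulses must lie within the simulation span")
    n = int(round(t_end / p.dt))
    edges = p.dt * np.arange(n + 1)
    d1_imp = np.histogram(d1, bins=edges)[0].astype(float)
    a2a_imp = np.histogram(a2a, bins=edges)[0].astype(float)
    if a2a.size:
        tgrid = p.dt * np.arange(n)
        idx = np.searchsorted(np.sort(a2a), tgrid, side="right") - 1
        prev = np.where(idx >= 0, np.sort(a2a)[np.maximum(idx, 0)], -np.inf)
        a2a_recent = (tgrid - prev) < A2A_CLAMP_WINDOW
    else:
        a2a_recent = np.zeros(n, dtype=bool)
    t1, t2, t3 = (float(x) for x in p.thresholds)
    f1, f2, f3 = (float(x) for x in p.mode_frequencies)
    level, hyper, rdrive, mode, licks = _core(
        d1_imp, a2a_imp, a2a_recent, p.dt, p.fill_gain, p.discharge_gain,
        math.exp(-p.leak_rate * p.dt), t1, t2, t3, f1, f2, f3, p.cap,
        p.rebound_gain, p.rebound_decay, float(initial_level))
    return SimulationResult(p.dt * np.arange(n), level, hyper, rdrive, mode, licks)


def evoked_frequency_curve(params: Optional[IntegratorParams] = None,
                           stim_frequencies: Sequence[float] = (5.0, 10.0, 25.0, 50.0),
                           duration: float = 1.0,
                           nfft: int = 2000) -> dict:
    """Dominant evoked licking frequency per D1 stimulation frequency.

    Simulates a 1-s pulse train per stimulation frequency and takes the
    lick-PSD peak over the stimulation-plus-persistence epoch (zero-padded
    spectrum for sub-Hz resolution).  The curve is non-decreasing and
    saturates at the pattern-generator cap: high stimulation frequencies all
    land in the top discrete mode, and 5 Hz stimulation does not produce
    5 Hz licking (no one-to-one pulse-to-lick mapping).
    """
    from .io_events import LickTrain
    from .rate_spectral import lick_psd, peak_frequency

    p = params or IntegratorParams()
    out = {}
    for f in stim_frequencies:
        res = simulate(d1_pulses=pulse_train(f, duration), params=p,
                       t_end=duration + 3.0)
        train = LickTrain(res.lick_times, f"cpg_{f}")
        psd = lick_psd(train, epoch_starts=[0.0, 1.0], epoch_len=1.0, nfft=nfft)
        out[float(f)] = peak_frequency(psd)
    return out


def post_offset_persistence(params: Optional[IntegratorParams] = None,
                            stim_frequency: float = 25.0,
                            duration: float = 1.0) -> float:
    """Seconds the integrator stays above theta1 after the last D1 pulse.

    Strictly increasing in stimulation frequency until the charge saturates;
    with a single pre-charge I0 and no input it has the closed form
    ``ln(I0 / theta1) / leak_rate``.
    """
    p = params or IntegratorParams()
    p.validate()
    pulses = pulse_train(stim_frequency, duration)
    tail = max(10.0, 5.0 / p.leak_rate)
    res = simulate(d1_pulses=pulses, params=p, t_end=float(pulses[-1]) + tail)
    s_last = int(round(pulses[-1] / p.dt))
    below = np.flatnonzero(res.level[s_last:] < p.thresholds[0])
    if below.size == 0:
        raise RuntimeError("integrator never decayed below theta1; extend the tail")
    return float(below[0]) * p.dt
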