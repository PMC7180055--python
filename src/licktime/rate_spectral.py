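"""Trial-aligned lick-rate estimation and frequency-domain analysis.

Rate traces are 100-ms-binned lick counts converted to Hz and smoothed with
a Gaussian kernel; spectra are per-epoch periodograms of the binarized lick
train averaged across epochs, summarised as a peak frequency and as percent
occupancy of the canonical licking bands (4–6, 6–8, 8–10 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter1d

from .io_events import LickTrain

#: Default Gaussian smoothing sd.  A "1 s wide" kernel is read as the ±2·sd
#: core spanning 1 s, i.e. sd = 0.25 s, with support truncated at ±2 s.
DEFAULT_SMOOTHING_SD = 0.25
DEFAULT_BIN_WIDTH = 0.1

#: Non-overlapping licking frequency bands (Hz): half-open [lo, hi), with the
#: top band closed at 10 so a 10 Hz fundamental counts as in-band.
LICK_BANDS: Tuple[Tuple[float, float], ...] = ((4.0, 6.0), (6.0, 8.0), (8.0, 10.0))

#: Search band for the dominant licking frequency; excludes DC and
#: stimulation-train artifacts above the CPG range.
PEAK_SEARCH_BAND = (2.0, 12.0)


@dataclass
class RateTrace:
    """Binned, optionally smoothed lick rate on a trial-aligned axis."""

    bin_centers: np.ndarray   # s, relative to the alignment event
    rate: np.ndarray          # Hz per bin
    bin_width: float = DEFAULT_BIN_WIDTH
    smoothing_sd: float = 0.0
    sem: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.rate)


@dataclass
class PSDResult:
    """Averaged lick power spectrum across analysis epochs."""

    frequencies: np.ndarray
    power: np.ndarray
    normalization: str = "raw"     # "raw" | "percent_of_total"
    n_epochs: int = 0
    n_flagged: int = 0             # epochs with < 2 licks (contributed zeros)


def rate_trace(licks: LickTrain, align_time: float,
               window: Tuple[float, float],
               bin_width: float = DEFAULT_BIN_WIDTH,
               smoothing_sd: float = DEFAULT_SMOOTHING_SD) -> RateTrace:
    """Lick rate in Hz on ``window`` (seconds relative to ``align_time``).

    Counts per ``bin_width`` bin are divided by the bin width; smoothing
    (``smoothing_sd > 0``) convolves with a Gaussian kernel truncated at
    ±2 s support, zero-padded at the edges so total count is conserved up to
    edge truncation.
    """
    a, b = window
    if b <= a:
        raise ValueError(f"empty analysis window [{a}, {b}]")
    n_bins_f = (b - a) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-6:
        raise ValueError(f"bin width {bin_width} does not divide window length {b - a}")
    edges = align_time + a + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(licks.timestamps, bins=edges)
    rate = counts.astype(float) / bin_width
    if smoothing_sd > 0:
        sigma = smoothing_sd / bin_width
        truncate = 2.0 / smoothing_sd          # fixed ±2 s support
        rate = gaussian_filter1d(rate, sigma=sigma, mode="constant",
                                 truncate=truncate)
    centers = a + bin_width * (np.arange(n_bins) + 0.5)
    return RateTrace(centers, rate, bin_width, smoothing_sd)


def mean_rate(traces: Sequence[RateTrace]) -> RateTrace:
    """Per-bin mean rate and SEM across trials (identical grids required)."""
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0]
    for t in traces[1:]:
        if len(t) != len(ref) or not np.allclose(t.bin_centers, ref.bin_centers):
            raise ValueError("rate traces are on different time grids")
    stack = np.stack([t.rate for t in traces])
    mean = stack.mean(axis=0)
    if len(traces) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(traces))
    else:
        sem = np.zeros_like(mean)
    return RateTrace(ref.bin_centers.copy(), mean, ref.bin_width,
                     ref.smoothing_sd, sem=sem)


def lick_psd(licks: LickTrain, epoch_starts: Iterable[float],
             epoch_len: float = 1.0, fs: float = 500.0,
             nfft: Optional[int] = None) -> PSDResult:
    """Averaged periodogram of the lick train over 1-s analysis epochs.

    Each epoch's licks are binarized on a 1/fs grid (default 2 ms, 500 Hz),
    mean-subtracted, Hann-tapered, and transformed with a periodogram; the
    per-epoch spectra are averaged.  Epochs containing fewer than 2 licks
    contribute an all-zero spectrum and are counted in ``n_flagged``.  With
    1-s epochs and no padding the frequency resolution is 1 Hz; ``nfft``
    zero-pads for a finer grid.
    """
    starts = list(epoch_starts)
    if not starts:
        raise ValueError("need at least one analysis epoch")
    n = int(round(epoch_len * fs))
    nfft = nfft or n
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    acc = np.zeros_like(freqs)
    flagged = 0
    for s in starts:
        edges = s + np.arange(n + 1) / fs
        x = (np.histogram(licks.timestamps, bins=edges)[0] > 0).astype(float)
        if x.sum() < 2:
            flagged += 1
            continue
        f, p = _signal.periodogram(x, fs=fs, window="hann",
                                   detrend="constant", nfft=nfft)
        acc += p
    return PSDResult(freqs, acc / len(starts), "raw", n_epochs=len(starts),
                     n_flagged=flagged)


def band_occupancy(psd: PSDResult,
                   bands: Sequence[Tuple[float, float]] = LICK_BANDS,
                   total_band: Tuple[float, float] = (0.5, 20.0)) -> dict:
    """Percent of total (0.5–20 Hz) power within each licking band.

    Bands are half-open ``[lo, hi)`` except the last, which is closed at its
    upper edge (so 4–5.99, 6–7.99, 8–10).  If the spectrum carries no power
    in the total band the occupancy is undefined and NaNs are returned.
    """
    f, p = psd.frequencies, psd.power
    if f.max() < total_band[1]:
        raise ValueError("PSD must cover the full 0.5-20 Hz analysis range")
    total = p[(f >= total_band[0]) & (f <= total_band[1])].sum()
    out = {}
    for i, (lo, hi) in enumerate(bands):
        closed_top = i == len(bands) - 1
        mask = (f >= lo) & ((f <= hi) if closed_top else (f < hi))
        out[(lo, hi)] = (100.0 * p[mask].sum() / total) if total > 0 else np.nan
    return out


def band_amplitude(psd: PSDResult,
                   bands: Sequence[Tuple[float, float]] = LICK_BANDS) -> dict:
    """Peak PSD amplitude within each licking band (same edge rules).

    For a rhythmic point process the *integrated* power per harmonic line is
    nearly constant — timing jitter lowers a line's height but broadens it by
    the same factor — so only line height separates a fundamental from its
    harmonics.  Band-wise amplitude is therefore the quantity that shows
    which band the licking rhythm occupies; :func:`band_occupancy` reports
    the complementary percent-of-total-power normalization.
    """
    f, p = psd.frequencies, psd.power
    out = {}
    for i, (lo, hi) in enumerate(bands):
        closed_top = i == len(bands) - 1
        mask = (f >= lo) & ((f <= hi) if closed_top else (f < hi))
        out[(lo, hi)] = float(p[mask].max()) if mask.any() else np.nan
    return out


def peak_frequency(psd: PSDResult,
                   band: Tuple[float, float] = PEAK_SEARCH_BAND) -> float:
    """Frequency of maximal power within the 2–12 Hz licking range.

    Ties resolve to the lowest frequency (the fundamental).  Raises if the
    band carries no power.
    """
    mask = (psd.frequencies >= band[0]) & (psd.frequencies <= band[1])
    p = psd.power[mask]
    if not p.size or np.all(p == 0):
        raise ValueError(f"no spectral power in the {band} Hz band")
    return float(psd.frequencies[mask][np.argmax(p)])


def normalize_percent(psd: PSDResult,
                      total_band: Tuple[float, float] = (0.5, 20.0)) -> PSDResult:
    """Rescale power to percent of total power in ``total_band``."""
    f = psd.frequencies
    total = psd.power[(f >= total_band[0]) & (f <= total_band[1])].sum()
    if total <= 0:
        raise ValueError("zero total power; percent normalization undefined")
    return PSDResult(f.copy(), 100.0 * psd.power / total, "percent_of_total",
                     psd.n_epochs, psd.n_flagged)
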