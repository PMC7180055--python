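"""Lick power spectra: natural anticipatory licking vs evoked fast licking.

Builds 1-s analysis epochs of anticipatory licking (~5.5 Hz) and of
direct-pathway-evoked licking (~9.5 Hz), computes the averaged periodogram
for each, and reports the dominant frequency plus band measures for the
canonical 4-6 / 6-8 / 8-10 Hz licking bands.
"""

import numpy as np

import licktime as lt
from licktime.rate_spectral import (band_amplitude, band_occupancy, lick_psd,
                                    peak_frequency)


def jittered_bout_train(freq, n_epochs, rng):
    ts, starts = [], []
    for e in range(n_epochs):
        t0 = 10.0 * e
        t = t0 + rng.uniform(0, 0.2)
        while t < t0 + 1.2:
            ts.append(t)
            t += max(1.0 / freq + rng.normal(0, 0.01), 0.05)
        starts.append(t0)
    return lt.LickTrain(np.sort(ts)), starts


rng = np.random.default_rng(3)
for label, freq in [("anticipatory (~5.5 Hz)", 5.5),
                    ("evoked by 25 Hz stimulation (~9.5 Hz)", 9.5)]:
    train, starts = jittered_bout_train(freq, 80, rng)
    # 0.5 Hz grid (nfft padding): 5.5 Hz licking falls between the 1-Hz
    # grid points of the unpadded dialect
    psd = lick_psd(train, starts, nfft=1000)
    amp = band_amplitude(psd)
    occ = band_occupancy(psd)
    print(label)
    print(f"  dominant frequency: {peak_frequency(psd):.1f} Hz")
    for band in amp:
        print(f"  band {band[0]:.0f}-{band[1]:.0f} Hz: "
              f"amplitude {amp[band]:.2e}, {occ[band]:.1f}% of total power")
# The dominant band moves from 4-6 Hz to 8-10 Hz under stimulation: band
# amplitude separates the fundamental from its harmonics, while percent
# power spreads across harmonic lines of the rhythmic point process.
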