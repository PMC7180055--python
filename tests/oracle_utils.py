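"""Independent oracles used by the test suite.

These are deliberately naive implementations (exhaustive search, direct
formulas, fine-grid inversion) kept separate from the package so they can
arbitrate its outputs.
"""

import math

import numpy as np


def exhaustive_changepoints(x, penalty=None):
    """Minimum penalized-cost segmentation with at most 2 changepoints.

    Brute force over all single indices and index pairs (O(n^2)), with the
    same L2 segment cost and per-changepoint penalty as the package default.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if penalty is None:
        penalty = 2.0 * math.log(n) * np.var(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):
        if j <= i:
            return 0.0
        return (ss[j] - ss[i]) - (s[j] - s[i]) ** 2 / (j - i)

    best = (cost(0, n), [])
    for i in range(1, n):
        c = cost(0, i) + cost(i, n) + penalty
        if c < best[0]:
            best = (c, [i])
    for i in range(1, n - 1):
        left = cost(0, i)
        for j in range(i + 1, n):
            c = left + cost(i, j) + cost(j, n) + 2 * penalty
            if c < best[0]:
                best = (c, [i, j])
    return best[1]


def planted_shift_signal(rng, max_bins=200, noise_sd=1.0):
    """Random signal with 0-2 planted mean shifts (>= 10-bin segments)."""
    n = int(rng.integers(30, max_bins + 1))
    k = int(rng.integers(0, 3))
    while True:
        bps = sorted(rng.integers(10, n - 9, size=k).tolist())
        if k < 2 or bps[1] - bps[0] >= 10:
            break
    levels = [rng.uniform(0, 3)]
    for _ in range(k):
        step = rng.uniform(2.5, 6.0) * rng.choice([-1.0, 1.0])
        levels.append(max(levels[-1] + step, 0.0))
    sig = np.empty(n)
    bounds = [0] + bps + [n]
    for seg, lvl in enumerate(levels):
        sig[bounds[seg]:bounds[seg + 1]] = lvl
    sig += rng.normal(0, noise_sd, size=n)
    return sig, bps


def gaussian_envelope_licks(center, sd, peak_rate, t0, t1, grid=1e-4):
    """Deterministic lick train with Gaussian-envelope intensity.

    Licks are placed where the cumulative intensity crosses k + 0.5 (fine-
    grid inversion), so the empirical rate trace follows the envelope with
    no sampling noise.
    """
    t = np.arange(t0, t1, grid)
    lam = peak_rate * np.exp(-((t - center) ** 2) / (2 * sd**2))
    cum = np.cumsum(lam) * grid
    n = int(np.floor(cum[-1] - 0.5))
    targets = np.arange(n + 1) + 0.5
    return np.interp(targets, cum, t)


def grid_search_gaussian_fit(t, y, mu_grid, sd_grid):
    """Best (amplitude, mean, sigma) by exhaustive grid search.

    For fixed (mu, sigma) the optimal amplitude is the linear least-squares
    solution a = <y, g> / <g, g>.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    best = (np.inf, None)
    for mu in mu_grid:
        for sd in sd_grid:
            g = np.exp(-((t - mu) ** 2) / (2 * sd**2))
            denom = float(g @ g)
            if denom == 0:
                continue
            a = float(y @ g) / denom
            r = float(((y - a * g) ** 2).sum())
            if r < best[0]:
                best = (r, (a, mu, sd))
    return best[1]


def skewness_moment_formula(x):
    """Third standardized sample moment, direct formula."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    return m3 / m2**1.5
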