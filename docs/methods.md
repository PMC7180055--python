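# Methods

`licktime` analyzes licking behavior of head-fixed mice on a fixed-time
(FT) reinforcement schedule: a drop of reward every 10 s, occasional
unrewarded peak-probe trials to expose the animal's internal interval
estimate, and optional 1-s optogenetic stimulation of the striatal direct
(D1) or indirect (A2A) pathway at fixed offsets from reward.  Because no
public dataset exists for this task, the package ships a synthetic-session
generator whose output carries the statistical structure the analyses
assume, plus per-trial ground truth so every stage can be scored by
parameter recovery.

## Data model and ingest

All times are float seconds on one session clock.  Lick timestamps are
debounced with a greedy scan that keeps a lick iff it falls ≥ 8 ms after the
previously *kept* lick; the greedy-retained variant (rather than comparing
against the raw predecessor) matches the debouncing intent and is
idempotent, which the raw-predecessor variant is not.  Trials live in a
tidy table (reward time, kind ∈ {fixed, peak}, laser onset/duration/
frequency, probe duration); sessions round-trip exactly through an
events-CSV + YAML-sidecar directory (floats written as `%.17g`, parsed in
round-trip mode).  Unless an analysis states otherwise it runs on the first
⌈N/2⌉ trials (ceiling, so odd sessions keep at least half) to limit
motivational drift; quartile and session-half analyses use the full session
by construction, and peak-shift curves use the full session to maximize
probes per condition.

## Synthetic sessions

**Scheduler.**  Three plain FT trials, then a decision point drawn
0.3 / 0.3 / 0.3 (laser-normal, laser-probe, plain-probe) with probability
0.1 of an immediate redraw, so each outcome is realized with probability
0.3·Σ₀.1ᵏ = 1/3.  Probe trials last 30 s plus a Gamma(shape 2.5, scale 4)
draw (mean extra 10 s); the consecutive-reward counter restarts after the
probe's terminal reward.

**Licking.**  A bout-level renewal model, not a homogeneous Poisson
process, because the downstream analyses (bout onsets, rhythm spectra)
require rhythmic structure.  Within a bout the tongue is a jittered
metronome: ILI = 1/frequency + N(0, jitter sd), truncated at 50 ms to
respect the ~10 Hz ceiling of the lick pattern generator.  Defaults:
anticipatory bouts at 5.5 Hz starting |N(3, 1)| s before each reward,
consummatory bouts at 7 Hz for 2 s after it, probe-trial peak bouts at
5.5 Hz spanning ±2 s around a centre drawn N(reward + 10 s, 1 s), sparse
0.1 Hz baseline licking, ILI jitter 10 ms.  One master seed spawns an
independent substream per trial, so any trial regenerates in isolation.

**Stimulation effects.**  `d1_evoke` adds an evoked bout during the laser
second — onset latency and lick frequency mapped from stimulation
frequency (latency falling, frequency rising and capped at 10 Hz) — and
persists 0.5 s past offset.  `a2a_suppress` deletes licks during
stimulation and, with probability 2/3, injects a post-offset rebound bout
whose latency map shrinks in mean and spread with stimulation frequency.
Clock-level consequences on probe trials are expressed through the peak
bout: `reset` re-centres it at stimulation onset + interval; `pause`
delays it by the stimulation duration; `pause_plus_rebound` additionally
delays it by the rebound duration on rebound-recovery trials, while on
rebound-initiation trials the peak bout starts at the rebound itself
(widening the peak without moving its centre).  The three probe outcomes
(recovery / initiation / no-rebound) are drawn equally likely by default.
A linear satiety drift (default slope 0, i.e. stationary unless asked for)
inflates evoke/rebound latencies and deflates rebound probability across
the session, which is the minimal mechanism that reproduces the quartile
and session-half trends.

The generator emulates bout rhythmicity, anticipatory ramping, probe-peak
timing, and injectable stimulation effects; it does not emulate lick-force
waveforms, inter-animal variability, reward-magnitude effects, or
within-bout frequency drift.  Tests passing on it therefore validate the
*measurement pipeline* (that each analysis recovers what was injected),
not claims about real mice.

## Rate traces and spectra

Rates are lick counts in 100-ms bins divided by the bin width, smoothed
with a Gaussian kernel.  The kernel's "1-s width" is read as sd = 0.25 s —
the ±2·sd core spans 1 s — with support truncated at ±2 s and zero padding
at the window edges, so mass is conserved except within ~0.5 s of an edge
(analyses that need edge fidelity use unsmoothed counts).

Spectra follow a configurable dialect (the original tool's parameters are
unpublished): each 1-s epoch is binarized on a 2-ms grid (500 Hz),
mean-subtracted, Hann-tapered, and periodogram-transformed; epochs average
into one spectrum (epochs with < 2 licks contribute zeros and are
flagged).  The unpadded grid step is 1 Hz; `nfft` zero-pads for finer
grids, which matters whenever the licking frequency falls between grid
points (e.g. 5.5 or 9.5 Hz).  The dominant licking frequency is the power
argmax restricted to 2–12 Hz (excluding DC and stimulation-train
artifacts), ties resolving to the lowest frequency.

Two band measures cover the canonical 4–6 / 6–8 / 8–10 Hz licking bands
(half-open [lo, hi), top band closed at 10): `band_occupancy` is percent
of total 0.5–20 Hz power per band, and `band_amplitude` is the peak PSD
height per band.  They answer different questions.  For a rhythmic point
process the *integrated* power per harmonic line is nearly invariant to
timing jitter — jitter lowers a line's height but broadens it by the same
factor — so percent-power occupancy cannot separate a 4 Hz fundamental
from its 8 Hz harmonic.  Line *height* does: the fundamental is always the
narrowest, tallest line.  Band amplitude is therefore the right statistic
for "which band does the rhythm occupy", and occupancy for "how
concentrated is the rhythm".

## Single-trial peak detection

For each probe trial, a 20-s window after the initiating reward is binned,
smoothed, and segmented by a penalized change-in-mean fit: exact dynamic
programming over at most 8 changepoints with L2 segment cost and a per-
changepoint penalty, default 2·log(n)·var(signal).  The penalty is a
design choice (the original tool's is unpublished) targeting the coarse
transitions of a 1-s-smoothed trace; it is exposed in `PeakConfig` and is
validated against an exhaustive minimum-cost oracle on signals with ≤ 2
planted shifts.  Changepoints are classified rising/falling by the mean of
5 bins after minus 5 bins before (clipped at edges; the ±5-bin span is
robust to bin noise and matches the 1-s smoothing scale); zero differences
are dropped.

The first rising changepoint and the next falling one delimit the
candidate peak.  A Gaussian is least-squares fit to the smoothed rate
between them (initialized at max/argmax/span-4, mean bounded to the
segment, sigma ∈ [0.1, 10] s); its mean is the single-trial peak time.
Validity requires duration ≥ 2 s and a *maximum* smoothed rate > 3 Hz
within the candidate (the maximum, rather than the mean, is the more
plausible reading of "licking rate had to exceed 3 Hz" for a bout whose
rate is by construction peaked).  On any failure — no rising/falling pair,
validity, or fit non-convergence — the window slides right 0.5 s, up to
5 times, then the trial is discarded.  No improvised segment ends: a
candidate without a falling changepoint fails even if the rate visibly
returns to baseline.  Because bins are 100 ms and changepoints live on bin
edges, detected durations quantize to 0.1 s; the duration criterion is
sharp at that resolution (a 1.6-s bout is rejected, a 2.6-s bout
accepted), not at the millisecond.

Stimulation trials shift the *initial* window start so stimulation-driven
licking is not scored as the peak: right by the stimulation delay on
direct-pathway trials stimulated at +3/+5 s, and by 6 s on rebound-
recovery trials after indirect-pathway stimulation.

Session statistics: width = end − start per trial; skewness = third
standardized moment of the pooled trial-relative lick times inside each
trial's peak; peak shift = mean laser-probe peak time minus mean no-laser-
probe peak time from the same session.

## Bouts, stimulation metrics, rebound classes

A bout onset is the session's first lick (no preceding ILI exists to
disqualify it) or any lick ≥ 1 s after its predecessor.  Stimulation
metrics use raw window counts, not smoothed traces (smoothing is reserved
for peak detection): Δ rate = count rate in the laser second minus the
mean rate over the identical trial-relative window on matched no-laser
trials of the same kind; evoked latency = first bout onset within the
laser second (missing if none, and missing trials are excluded rather
than zero-filled); rebound latency = first onset within the closed
[0, 3] s window after offset; post-offset count = licks in the 1 s after
offset, with the matched no-laser baseline.  Window boundaries are closed
deterministically.

Probe trials with mid-interval indirect-pathway stimulation classify by
onset pattern: no onset within 2 s of stimulation onset → `no_rebound`;
otherwise a second onset within (rebound, rebound + 8 s] → `recovery`,
else `initiation` (alias "absorption" accepted).  The three labels
partition every classified set.  Quartiles are assigned by laser-
presentation order (not reward count), splitting laser trials into four
ordinal blocks.

## Integrator–CPG model

The conceptual circuit model is a leaky integrator gating a discrete-mode
pattern generator.  No equations are published for it, so the package
adopts the smallest ODE exhibiting the qualitative claims, every constant
exposed in `IntegratorParams`:

    dI/dt = −leak·I,   I += fill_gain per D1 pulse,
                       I −= discharge_gain per A2A pulse,  I ≥ 0.

Decay between pulses is integrated with the exact exponential update, so
the free-decay phase matches the closed form to machine precision and
post-offset persistence from a charge I₀ equals ln(I₀/θ₁)/leak exactly.
Thresholds θ₁ < θ₂ < θ₃ (defaults 1.5, 2.2, 8.0 level units) map the level
to modes off / 5 / 7 / 9.5 Hz.  Defaults were chosen so that, with
fill_gain 1 per pulse and leak 1 s⁻¹: a single pulse stays subthreshold
(first-lick latency = time of the second pulse, hence strictly falling in
stimulation frequency); 5 Hz stimulation reaches the 7 Hz mode by its
third pulse (no one-to-one pulse-to-lick mapping); and only ≥ 25 Hz
stimulation reaches the top mode, saturating the evoked-frequency curve
near the 10 Hz cap.  The threshold→mode mapping is hypothesis, not
measurement; nothing quantitative is claimed for it beyond the cap and the
monotonicities.

Lick emission is a deterministic metronome: an off→on transition emits
immediately and starts the period; a mode change while licking keeps the
phase anchored at the last lick and switches the period (re-phasing on
every transition would let threshold chatter emit at the cap rate).
Emitted ILIs are additionally floored at 1/cap, making the 10 Hz cap a
hard invariant under arbitrary input.

Rebound is a separate low-pass state rather than a negative integrator
value (keeping I ≥ 0 clean): A2A pulses charge a hyperpolarization
variable H; while inhibition is ongoing (an A2A pulse within the last
0.25 s) the release drive R is clamped at zero; afterwards R relaxes
toward e·H while H decays, producing a transient suprathreshold burst
whose onset latency falls — and tightens — as the accumulated charge
grows.  The effective gating level is I + R.

The simulation core is a compiled (numba) per-step loop; with the default
dt = 1 ms a 3-s protocol simulates in tens of microseconds, so invariant
sweeps over 10⁴ randomized protocols are cheap.

## Numerical and scale choices

Problem sizes used by the test suite and the acceptance script — 200
no-stimulation probes, 100 clock-reset probes, 500 oracle signals, 300
constructed rebound trials, 10⁵ scheduler decision points, 10⁴ randomized
integrator protocols — were chosen so each recovery statistic's Monte-
Carlo error is several times smaller than the tolerance it is checked
against.  Ties in the changepoint DP resolve to fewer changepoints; ties
in `peak_frequency` to the lower frequency.  Degenerate inputs fail
loudly: empty analysis windows, all-zero fit segments, zero-power spectra
(occupancy returns NaN, never 0), sessions without matched no-laser
trials, fewer than 4 laser trials for quartiles, empty session halves.

## Known limitations

* The changepoint penalty and the spectral dialect are calibrated choices,
  not reproductions of the unpublished originals; results depending on
  them are dialect-dependent, which is why both are configurable and
  validated against oracles/synthetic truth rather than bit-compared.
* Group-level inferential statistics (ANOVA, post-hoc corrections) are out
  of scope; the package emits tidy per-trial tables for standard tools.
* One peak per probe trial: multi-peak trials report only the first
  rising/falling pair that passes validity.
* The integrator–CPG model is qualitative; its parameters are not fit to
  animal data.
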