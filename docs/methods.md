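# Methods

This note documents the models, parameters, and numerical choices behind
`blinklearn`: what the synthetic sessions emulate, how each analysis stage
is defined, and where the design was genuinely open.

## The recording model

A *session* is one day of delay eyeblink conditioning at one learning stage
(`initial`, `halfway`, `final`). The stimulus protocol is fixed by the
paradigm: a 350 ms tone CS defines time zero; a 100 ms air-puff US starts at
+250 ms and co-terminates with the CS; trials are cut from −1 s to +2 s
around tone onset; the orbicularis-oculi EMG is sampled at 5 kHz (15 000
samples per trial). A session holds 60 paired trials and 6 CS-alone probes
by default; probe positions are stored explicitly (never trial 0, and by
default non-adjacent so each probe has its own preceding paired trial).
Units belong to exactly one session — electrodes are withdrawn daily, so no
unit identity is tracked across stages. Units inhibited rather than
activated by the stimuli can be flagged (`suppressed_units`) and are
excluded from population analyses by default.

Timing invariants (e.g. CS/US co-termination) are checked with a 1e-9 s
tolerance because the defining sums (0.25 + 0.10 vs 0.35) are not exact in
binary floating point. Spike times are stored on disk as fixed 6-decimal
strings (microsecond precision); the generator rounds to the same grid, so
write → read round trips are bit-exact.

## Synthetic sessions

The generator's role is to produce sessions carrying the statistical
structure the analysis assumes, at parameters a practitioner would call
realistic, so that every downstream computation can be validated against
known ground truth.

**Spike trains.** Unit `u` on a trial fires as an inhomogeneous Poisson
process with rate

```
lambda(t) = g_u · b · [1 + cs·1(CS) + us·1(US, paired) + ramp(t) + late(t, paired)]
```

sampled by Lewis–Shedler thinning with a hard absolute refractory dead time
(default 2 ms; for constant rate the output rate is `lambda/(1+lambda·tau)`,
and tests use this dead-time-corrected expectation). `ramp(t)` rises
linearly from 0 at `ramp_onset_s` to `ramp_gain` at US onset and stays at
`ramp_gain` through the US interval, on paired *and* CS-alone trials: it is
the learned, predictive component, so it cannot depend on whether the puff
actually arrives. `late(t) = late_error_gain·exp(−(t−us_offset)/tau)` is
the long-lasting post-US error response; it is driven by the US and
therefore appears on paired trials only. `g_u` is a per-unit lognormal gain
(mean 1, sigma 0.8): real interpositus units span a wide firing range, and
this between-unit variance is what makes the two-sample US-omission
contrast properly conservative under no effect — with identical units it
would reject at exactly its nominal rate per bin and "no difference in the
US window" would never be observable.

**Stage presets.** Baselines follow the reported spontaneous means per
10 ms bin (8.7 / 7.8 / 5.3 Hz). Gains are free parameters chosen once for
the qualitative trajectory; the magnitudes are assumptions, not claims:

| stage   | b (Hz) | us  | ramp (onset)   | late (tau)  | CR prob | CR latency | UR amp |
|---------|--------|-----|----------------|-------------|---------|------------|--------|
| initial | 8.7    | 2.3 | 0 (–)          | 3.0 (0.45 s)| 0.07    | 220 ms     | 8      |
| halfway | 7.8    | 1.9 | 0.8 (150 ms)   | 1.5 (0.40 s)| 0.25    | 180 ms     | 6      |
| final   | 5.3    | 0.0 | 7.0 (40 ms)    | 1.5 (0.40 s)| 0.81    | 120 ms     | 3      |

The final stage has `us_gain = 0` deliberately: once conditioned, firing in
the US window is the predictive ramp, identical on paired and CS-alone
trials, which is what makes the US-omission contrast silent there. The tone
gain is 0 at every stage — before learning the tone evokes nothing, and
after learning the response is modelled entirely by the ramp.

**EMG.** Traces are zero-mean Gaussian noise (sd 1) plus rectangular
envelopes of amplitude-modulated noise: every paired trial carries an
unconditioned reflex burst 10 ms after US onset, and any trial carries,
with the stage's CR probability, a conditioned burst whose onset is drawn
from a normal (sd 30 ms) truncated to [50 ms, US onset). Bursts last 200 ms
— an eyelid-closing burst persists for a few hundred ms, so the conditioned
burst merges into the reflex burst as in real averaged blink EMG. The
reflex amplitude declines across stages (8 → 6 → 3 noise SDs) because a
conditioned closure already shields the cornea when the puff arrives.
These are envelope-level surrogates, not motor-unit models: the analysis
only ever consumes rectified envelopes.

**Reproducibility.** Every (stream, stage, trial, unit) tuple seeds its own
counter-split generator (`numpy` `SeedSequence` spawn keys), so output is
bit-identical for a given seed and independent of generation order.

**What the generator does not emulate.** No inter-trial 60 s timeline, no
slow within-session drift or learning inside a session, no bursting or
oscillatory spike-train structure beyond refractoriness, no correlation
between a trial's neural ramp and the presence of its behavioural CR, and
no motor-unit waveforms. Passing tests therefore demonstrate that the
analysis recovers the structure this model encodes — rates, latencies,
incidences, delays — not that it is robust to every property of real
recordings.

## Analysis stages

**EMG preprocessing.** Linear detrend (configurable to mean-only), then a
zero-phase 4th-order Butterworth high-pass at 100 Hz (`sosfiltfilt`; zero
phase so the filter cannot bias onset estimates), then absolute value.

**Changepoint onset.** Exhaustive single-changepoint search minimizing the
two-region sum of squared deviations from region means, computed in O(n)
with prefix sums; ties break to the smallest split index, and the onset is
the time of the first post-split sample. The search domain is a parameter
defaulting to the whole trace; the *pipeline* restricts it to
[epoch start, US offset + 100 ms], because a single two-region split on the
full 3 s epoch locks onto the largest step in the trace, which for a brief
response can be its offset rather than its onset. The domain deliberately
includes the pre-CS second — spontaneous blinks can put the best split
before the tone.

**CR scoring.** Threshold rule: the rectified trace must exceed
`baseline mean + 3·SD` (baseline = pre-CS segment) continuously for ≥ 10 ms
with the run starting in [50 ms, US onset). The rule is applied to a 5 ms
centered moving-average envelope of the rectified trace: single rectified
noise samples cannot stay above a 3 SD threshold for 50 consecutive
samples, so raw-sample thresholding would miss genuine modulated-noise
bursts; the envelope width is exposed (0 disables). With a zero-variance
baseline the threshold degenerates and falls back to an absolute floor,
flagged in the result. The threshold constants are conventions, not
measurements, and are exposed as configuration.

**PSTH tracing.** Counts are trial-averaged per unit on the half-open 10 ms
grid (left edge labels the bin; a spike exactly at the epoch end is counted
in the last bin so spike counts are conserved). The per-bin test is a
two-sided one-sample Wilcoxon signed-rank across units with zeros
discarded; an all-zero column yields p = 1. The pipeline tests counts after
subtracting each unit's mean spontaneous-window bin count: a test of "is
this bin different from zero" is uninformative for units with ongoing
baseline firing, and onset latencies are only meaningful as departures from
baseline. BH correction uses the step-up procedure (via `statsmodels`),
with the adjusted p-values additionally smoothed by a centered moving
average (span 0.8 of the bin count, forced odd, truncated at the edges) —
*for display only*; the significance mask and the onset latency always use
the unsmoothed adjusted p-values. The default FDR level is q = 0.05;
latency-focused analyses use q = 0.01. The FDR level genuinely matters for
latencies: with ~100 truly active bins, BH at q admits on the order of
`q/(1−q) × 100` false discoveries spread over the null bins, and at
q = 0.05 the *first* significant bin is frequently one of them. Both levels
are exposed.

**Windows and ISIs.** The four windows are half-open: spontaneous [−1, 0),
CS [0, 0.25), CS-US [0.25, 0.35), late [0.35, 2) s. The nominal "251 ms"
left edge of the CS-US window is read as the bin starting at 250 ms — the
only reading consistent with a 10 ms grid. Window statistics pool per-unit
trial-averaged bin counts; stage comparisons use the two-sided Wilcoxon
rank-sum test (exact for small untied samples). ISIs are differences of
consecutive spikes with *both* spikes inside the window, histogrammed in
4 ms bins; the mode is the center of the tallest bin (ties to the smallest
bin), median and mean are computed on the raw ISIs.

**Lag scan.** The 35-bin population spike profile over [0, 0.35) is
correlated (Pearson) with 35-bin segments of the binned full-epoch EMG
taken at [lag, 0.35 + lag) for lags −100…+180 ms in 10 ms steps. Keeping
the segment length constant (sliding over the full epoch rather than
truncating the overlap) keeps r comparable across lags. Positive lag means
the EMG segment is later in time, i.e. spikes lead the muscle. Zero-variance
segments yield an undefined (NaN) r excluded from the best-lag search; ties
at the maximum break toward the smallest |lag|, then the more negative lag.
Under the default presets the final-stage best lag computes to about
−20 ms: the averaged EMG rise (the CR-latency distribution function) is
centered slightly earlier than the long linear spike ramp, even though the
spike *onset* precedes the EMG onset by tens of ms. The lag scan aligns
whole profile shapes, not onsets — the two readouts answer different
questions and can legitimately disagree in sign.

**Contrasts.** Between-stage comparisons use a pooled-variance two-sample
t-test per 10 ms bin across units at an uncorrected threshold (default
alpha 0.01), with an optional BH flag; zero-variance bins map to p = 1
(equal constants) or p = 0 (different constants). The US-omission analysis
selects, for each CS-alone probe, the nearest preceding paired trial;
adjacent probes would share one paired trial, which is then used once (the
mismatch is warned about) so the subsets stay one-to-one on distinct
trials. The per-bin test is configurable between the two-sample t (default)
and a paired signed-rank across units.

**Lead time.** `EMG onset − neural onset`, positive when spikes precede the
muscle.

## Problem sizes

The test suite and the acceptance script size their simulations to run on a
single CPU in minutes while keeping every statistical check properly
powered: 50–60 units per session for population analyses (matching the
~60 units per stage a recording campaign yields), 500 replicates for
calibration and recovery rates, 600 paired trials for the CR-probability
recovery (binomial 99% CI), 1000 random signals for the changepoint oracle,
and full sign/assignment enumeration up to n = 10 / n = 8 for the exact
small-sample test oracles. Several spike-only checks use a 500 Hz EMG grid
since the traces are not consumed there.

## Known limitations

- The changepoint model fits exactly one split; a trace whose largest step
  is not the response onset (e.g. a dominant reflex burst after a weak
  conditioned component) yields the reflex onset. This is visible in the
  halfway-stage preset, whose averaged-EMG onset stays at the reflex
  latency rather than moving forward.
- CR scoring with a fixed 3 SD/10 ms rule has essentially zero false
  positives at the generator's noise level but is not calibrated for
  heavy-tailed real EMG noise.
- The signed-rank trace treats units as the replication unit
  (trial-averaged counts); pooling trials instead would change both power
  and the meaning of the p-values.
- Exact small-sample signed-rank p-values are bounded below by `2/2^n`;
  with few units no bin can pass a stringent BH threshold over 300 bins,
  so latency tracing needs on the order of 20+ units.
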