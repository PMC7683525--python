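# Methods

## The Stability Index

For a behavior *b* on day *d*, let `A_b^d(x)` be the amount of activity in
minute *x* (*x* = 1..*M*, *M* = 1440).  The day's timing profile is its
normalized cumulative sum

    C_b^d(x) = Σ_{i≤x} A_b^d(i) / Σ_{i≤M} A_b^d(i),

the fraction of the day's activity done by minute *x*.  Two days are
compared by the mean absolute difference of these curves,

    D_b(d1, d2) = (1/M) Σ_x |C_b^d1(x) − C_b^d2(x)|,

and the Stability Index of a period *P* of days is

    SI_b(P) = 1 − median{ D_b(i, j) : i, j ∈ P, i ≠ j }

over unordered pairs.  Higher SI means a more repeatable daily timing
pattern.  Because the comparison happens on cumulative curves, a schedule
that merely slides by δ minutes changes `D` by at most δ/*M*: timing noise
of a few minutes is nearly invisible, whereas comparing hourly histograms
(the `hourly_raw_distance` baseline) saturates completely when a single
event crosses an hour boundary.  This shift bound and the hour-mark
pathology are both asserted in the test suite.

Numerical conventions:

- The median over an even number of pairs is the mean of the two middle
  values.
- Days with zero total activity have no defined cumulative curve and are
  excluded from the pair set rather than imputed; with fewer than two
  usable days the SI is undefined.  Imputing a flat curve would
  manufacture stability for empty days.
- The top of each cumulative curve is pinned to exactly 1 to keep the pair
  distances free of accumulated floating-point drift.
- `D` is symmetric, bounded by (M−1)/M, and SI therefore lies in
  (1/M, 1] when defined.
- Day length is a free parameter of the metric functions so exhaustive
  oracle tests can run on toy instances (length 24); all real use is 1440.

The *absolute* variant replaces `C` by the un-normalized cumulative sum and
runs the same pipeline (same zero-day exclusion, same 1 − median; the raw
median distance is reported alongside because the value can leave [0, 1]).
It is volume-sensitive by construction — two days with identical timing but
different totals diverge — and exists purely as a diagnostic: the test
suite asserts that across a synthetic cohort the absolute variant is more
correlated with the behavior mean than the normalized one for every
behavior, i.e. the normalized SI carries timing information orthogonal to
volume.

## Binning

Streams arrive as timestamped events.  Instantaneous events (a message, an
ambient sensor reading) add their magnitude to the minute containing the
timestamp; period events (calls, stillness, sleep...) contribute one unit
per covered minute with proportional fractions at the boundaries, so mass
is conserved exactly and a per-second rasterizer reproduces the result.
Days are local calendar days — routine is a clock-time concept — and
periods crossing midnight are split across the two days.  Minute *x* is
1-based and covers [x−1, x) minutes after midnight.

## Filtering and features

A *good day* has strictly more than 19 h of sensing coverage.  Each EMA
response anchors one candidate window: the 14 calendar days strictly
preceding `anchor − lead` (lead ∈ {0, 7, 14}; 7-day windows are a config
option).  Windows with fewer than 7 good days are dropped.  Per behavior,
features are computed over good days only: the SI, and the mean and
population SD (ddof = 0, configurable) of per-day totals.  Whether the
original analyses used all days or good days for the mean/SD is ambiguous;
good days are used here for consistency with the SI.  Participants are
retained when they have strictly more than 25 usable windows (counted
post-filter; the alternative reading — raw responses — is noted as
ambiguous), which guarantees the 15 training + 10 test points the
prediction experiments need.  The previous-EMA feature is the composite of
the response dated exactly 7 days before the anchor, with no
nearest-neighbour fallback.  Lead-time datasets are aligned by
intersecting (participant, anchor) keys across leads so the three
experiments see identical test points.

The EMA composite is the sum of the five negative items minus the sum of
the five positive items, each item in 0..3, giving a −15..15 scale with
higher = worse.

## Prediction experiments

All predictive models are gradient-boosted regression trees with 300
trees, maximum depth 3 and learning rate 0.17, fixed for every experiment
(a 10-fold-CV search mode exists but defaults off).  Test points are each
participant's 10 most recent windows; training uses the 5/10/15 windows
immediately preceding them.  Model arms: previous EMA; per-behavior
mean+SD; SI (with per-behavior missingness indicators, undefined SI
imputed as 0 — an out-of-range sentinel — at fit time only); SI+mean+SD;
and a baseline predicting the pooled training-target mean.  The
previous-EMA arm is evaluated only on points where that response exists,
with its n reported.  Errors are pooled across participants into one MAE;
uncertainty is a percentile bootstrap (1000 resamples of the pooled
per-point errors) and arms are compared by two-sided Wilcoxon signed-rank
tests on per-point absolute errors matched on (participant, anchor), with
p = 1 by convention when all differences vanish.  The reported Wilcoxon
statistic is the signed rank sum R⁺ − R⁻ so that swapping arms flips its
sign.  In the population experiments, the population pool is the other
participants' *training blocks* (never their test windows, to avoid
leakage); the combined arm appends a binary same-individual indicator, and
the individual-only arm with zero user examples falls back to the pooled
training-target mean.

Pooled (observation-level) correlations are primary, matching the design
of the correlation analysis being emulated; per-behavior Pearson r against
the composite is Bonferroni-corrected with family = number of behaviors
tested (17 by default).

## Synthetic cohort generator

The generator emulates the *structure* of a year-long smartphone-sensing
study of people with schizophrenia-spectrum disorders, with known ground
truth; it makes no attempt to reproduce that study's empirical numbers.

- **Latent symptoms.** Per participant, a trait offset ~ N(0, 1.0²) plus a
  daily AR(1) state (φ = 0.8, innovation SD 0.6, stationary SD 1.0).  The
  offset flows through everything downstream — chronically worse symptoms
  mean chronically looser routines and higher questionnaire scores — which
  is what makes personalized models valuable on the default cohort.
- **Routines.** Each behavior has a personal template of characteristic
  times (drawn once per participant) realized daily with Gaussian timing
  jitter σ_eff = σ_b · exp(β_b · s_t).  β_b > 0: worse symptoms loosen the
  routine (lower SI).  Default signs: positive β for messages, calls and
  unlocks; negative for stillness and ambient non-voice sound; zero
  elsewhere.  The sparse count behaviors carry far less timing information
  per day than dense period behaviors, so their |β| default is higher
  (1.2 vs 0.6) to produce comparable detectable effects; count events
  cycle deterministically through the sorted template so day-to-day
  variation reflects jitter rather than random slot choice.
- **Volumes.** Daily totals are moment-matched lognormals at
  cohort-typical scales (≈3.4 incoming messages, ≈467 still minutes per
  day; the two ambient scalar streams, absent from the magnitude table,
  use arbitrary sensor-unit defaults), independent of the latent process,
  so timing and volume information are separable by construction.
  Message counts use unbiased stochastic rounding; periods may cross
  midnight and are split by the binner, keeping calendar-day totals
  unbiased (verified to 3 standard errors at 365 days).
- **EMA.** Mon/Wed/Fri schedule, 37% missingness; items arise by monotone
  thresholding of the standardized latent level plus item noise
  (SD 0.5), with cutpoints (−0.8, 0.3, 1.3) chosen to keep item marginals
  spread over 0..3.
- **Coverage.** sensed_hours = 24 − Exponential(2.0) hours, clipped to
  [0, 24], giving roughly 8% bad days.
- **Determinism.** A fixed seed tree keyed by (seed, participant,
  behavior) means adding participants or behaviors never perturbs
  existing data; identical configs reproduce byte-identical CSVs.

What the generator does *not* emulate: raw sensor waveforms, weekday/
weekend structure, inter-behavior dependence beyond the shared latent
process, relapse events, or device artifacts.  Passing tests therefore
show that the pipeline recovers known generative structure at realistic
scales and noise levels — not that real data would yield these effect
sizes.

## Study conditions used by the tests

The property tests instantiate cohorts whose sizes are chosen to make each
mechanism identifiable:

- *Sign recovery*: the study-scale default — 13 participants × 365 days —
  yielding ≈1200 windows; all six coupled behaviors come out
  Bonferroni-significant with the configured signs.
- *Null calibration*: overlapping windows and the persistent latent process
  shrink the effective sample size well below the window count, so the
  null (all β = 0) check uses 36 participants × 210 days on a six-behavior
  subset to bound spurious pooled |r| under 0.1.
- *Orthogonality*: 5 participants × 180 days (≈240 windows).
- *Heterogeneity*: 8 participants × 150 days with trait offsets of 2
  latent SDs and uncoupled behaviors, so symptom levels are not
  recoverable from features — individual data then always beats
  population data, and the reverse holds on an exchangeable cohort
  (no offsets, φ = 0.4, doubled couplings, item noise 0.25) where the
  shared feature→target mapping, not temporal recency, carries the
  signal.
- *Timing-only cohort* (constant daily totals, doubled couplings): the
  SI-only model beats both the population-mean baseline and the mean+SD
  model, demonstrating that the index captures predictive information
  volume features cannot.

## Known limitations

- The pooled correlations inherit the usual caveat of overlapping windows
  and autocorrelated symptoms: nominal p-values overstate the effective
  sample size.  Bonferroni correction and the many-participant null check
  mitigate but do not remove this.
- Ambient scalar streams are treated as per-minute non-negative amounts;
  occurrence-indicator treatment would change their SI.
- Civil-time days are binned into 1440 slots by clock time with no
  daylight-saving adjustment.
- The absolute-variant normalization (1 − median, possibly negative) is
  one of several defensible choices; the raw median distance is exposed so
  any alternative can be derived.
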