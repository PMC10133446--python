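# Methods

## Stimulus model

Every tone is a harmonic complex of `N = 20` partials at `n·f0` with
amplitude weights `1/n^α`, summed in sine phase (all phases zero — the
choice is free acoustically and makes synthesis deterministic). The
spectral centroid of that weight profile is

```
SC(α) = f0 · Σ_{i=1..N} i·i^{-α} / Σ_{i=1..N} i^{-α},
```

strictly decreasing in `α` for `N ≥ 2`. The reference distractor is defined
by `α = 3` and `SC = 512 Hz`, which pins the nominal fundamental at
`f0 ≈ 385.20 Hz`; that value is computed at load time, never hard-coded.
Singletons are specified by target SC and the exponent is recovered by
root-finding (Brent's method on the monotone map; relative SC error below
1e-9, verified to 1e-6 by tests over `α ∈ [0, 10]`). Specifying singletons
by SC rather than by a fixed exponent is deliberate: a single fixed `f0`
cannot make both an `α = 2` tone and an 822/512 Hz centroid ratio hold
simultaneously, so SC values are treated as the authoritative description
throughout.

Roughness is sinusoidal amplitude modulation of the whole complex,
`(1 + m·cos(2π·50·t))`, with depth `m ∈ [0, 1]`. After modulation the tone
is re-peak-normalized: presentation level is controlled by loudness
equalization in the real experiment and is carried here as per-tone dB SPL
metadata, so synthesis keeps digital peaks level-independent. Tones carry
5 ms linear on/off ramps (the ramp shape is not otherwise constrained;
linear is the simplest monotone choice). Durations: distractor 170 ms,
short/long targets 120/220 ms. Sequences place five tones at a constant
230 ms inter-onset interval; with these durations nothing overlaps, and any
overlapping tails from custom configurations are summed then renormalized.
Harmonics at or above Nyquist are dropped silently by default (at 44.1 kHz
and `f0 ≈ 385 Hz` the 20th harmonic sits near 7.7 kHz, far below Nyquist);
a strict mode raises instead, naming the harmonic.

Two measurement oracles close the loop in tests: a Hann-windowed rFFT
centroid of the steady-state segment (matches the closed form within 2% for
`α ∈ {0,1,2,3}`), and a Hilbert-envelope demodulator whose projection onto
the 50 Hz modulator recovers `m` within ±0.02.

## jnd ladders and designs

Perceived deviations are measured in just-noticeable differences: 5% of SC
per brightness jnd and 0.10 of modulation depth per roughness jnd. Two
ladder rules appear in the configured designs, each chosen because it
reproduces that design's published feature values exactly after rounding:

* additive — `base·(1 + 0.05·k)`: 512 Hz × {1,2,5,10} → 538, 563, 640,
  768 Hz; depths 0.1, 0.2, 0.5, 1.0;
* compound — `base·(1.05)^k`: 512 Hz × {2,5} → 564, 653 Hz; 631 Hz × {2} →
  696 Hz.

The symmetric design around 631 Hz keeps its four values literal (512, 569,
696, 768 Hz, recorded as −4, −2, +2, +4 jnd): no single rule generates all
four, and only the +2 step matches the compound rule, so the configuration
lists them verbatim rather than forcing a rule.

Five designs ship as versioned YAML configuration: `exp1` (6 blocks × 60
trials, one bright singleton at SC 822 Hz present on 50% of trials; its
abscissa for the combined regression is its additive-ladder equivalent,
(822/512 − 1)/0.05 ≈ 12.11 jnd), and `exp2`–`exp5` (8 × 80, four singleton
variants at 20% each plus 20% singleton-absent). The combined design
(`exp5`) crosses SC ∈ {564, 653} Hz with depth ∈ {0.2, 0.5}, giving summed
deviations {4, 7, 7, 10} jnd. Trial counts for the symmetric design are not
published; it uses the same 8 × 80 structure as the other four-variant
designs.

Every block satisfies its quotas exactly: targets 50/50 short/long and
50/50 position 3/4, the singleton fraction split equally over variants, and
singleton-before/after 50/50 within each variant (the singleton always sits
adjacent to the target, and the first tone of a sequence is always a
distractor). The three assignments are shuffled independently with a seeded
generator and zipped; a fully crossed factorial is impossible for 60-trial
blocks (60 is not divisible by the 16-cell factorial), and the source
procedure only promises random distribution, so exact marginal quotas with
a random joint is the faithful construction. Impossible quotas (odd counts,
variant counts that do not divide) raise with the required divisibility.
Each trial also draws a fundamental-frequency jitter, uniform over a 20 Hz
total width around nominal `f0` — the width is configurable because the
description of the jitter distribution is ambiguous; all five tones of a
trial share the jittered `f0`.

## Observer model

The generator is deliberately descriptive, not mechanistic (no diffusion
model, no learning): it exists so the analysis has data whose ground truth
is known.

* RT on a non-lapse trial: `mu + β_b·|d_b| + β_r·|d_r| (+ position term) +
  ε`, `ε ~ N(0, σ²)` truncated below at 0; RTs at or past the 3000 ms
  deadline become unanswered trials (response `none`, RT missing). RTs are
  measured from target onset, and the deadline is interpreted on the same
  clock.
* Defaults: `mu = 985 ms` with a 140 ms between-participant SD and
  `σ = 150 ms` within — the absent-singleton mean and spread of the
  single-singleton dataset; slopes default to 14.0/12.4 ms per jnd.
* Errors: probability `0.162 + 0.0066·(|d_b| + |d_r|)`, clipped to [0, 1].
  The gain is calibrated once so the ≈12.1 jnd singleton of the
  single-singleton design yields ≈16% vs ≈24% error rates, mirroring the
  observation that error rates track the RT costs.
* Lapses (default 2%): response is a fair coin and RT uniform on
  [0, 3000) ms — these are what the floor/deadline/2-SD rules exist to
  catch.
* The cost combination across features is additive by default; a `max`
  combination is available as the non-additive alternative. The
  before/after position term defaults to 0 ms because its published
  magnitude is unknown; it is a single configurable additive constant.

Per-participant parameters are drawn from child seeds spawned off the
cohort seed, so logs are reproducible and extending a cohort never changes
existing participants.

## Analysis pipeline

Cleaning, in order: unanswered trials are dropped; within each participant
× singleton-condition cell, answered trials more than 2 sample standard
deviations (ddof = 1) from the cell mean are dropped (cells under 3 trials
pass through with a warning); trials under 100 ms are dropped. Participants
with overall error rates at or above 40% are excluded before trimming. Note
the 2-SD rule is conservative in tiny cells — a single extreme value
inflates the cell SD enough to protect itself; this is a property of the
rule, not a bug, and the tests pin it.

Condition summaries are per participant × condition: mean and SD of correct
RTs, error rate, and LISAS = mean correct RT + (SD_RT/SD_error)·error
proportion, with sample SDs computed per participant per condition (the
score's exact variant is not pinned down in the literature; the
per-cell form is the one implemented and flagged here). Capture effects are
within-participant RT increases (condition mean − no-singleton mean);
condition-level means and SEs are taken across participants.

Inference: paired t-tests (two-tailed by default; the tail is an argument)
with Cohen's d = mean(diff)/SD(diff), step-down Holm adjustment for
families of comparisons, and minimum-n power for a paired/one-sample t as
the smallest n whose noncentral-t power reaches the target (one-tailed
d = 0.8, α = .05, power .8 → n = 12). Position and surprise contrasts are
paired t-tests on before-vs-after singleton trials and on singleton trials
preceded by absent-vs-present trials respectively.

The capture-law fit is ordinary least squares of RT increase on |deviation|
in jnd. `recover_capture_law` fits the participant-level points (one per
participant × condition) rather than the 4–5 condition means: the slope
estimate is identical in expectation and the standard error then reflects
between-participant variability, which is what the recovery criterion (±2
estimated SEs of the generating slope) is judged against. A constant
ordinate would make Pearson r undefined; that case is reported as slope 0
with a degenerate flag rather than NaN.

## Problem sizes and what passing shows

Recovery runs use 20 participants × 640 trials — the cohort and session
size of the four-variant designs — and finish in seconds. With `σ = 150 ms`
the brightness/roughness recoveries estimate the slope to ≈0.6–0.9 ms/jnd
(SE), and the combined design to ≈1 ms/jnd (its summed-jnd abscissa
{4,7,7,10} spans less range, so the slope is intrinsically less
constrained).

The generator shares its assumptions with the analysis (normal noise,
history-free trials, additive law), so recovery demonstrates that the
pipeline is unbiased and correctly wired — not that the law holds for human
listeners. Real RT distributions are right-skewed, participants fatigue and
adapt, and position effects exist; none of that is emulated by default. A
log-normal-like skew can be approximated by raising the lapse rate or
post-processing RTs, but the cleaning rules themselves are distribution-
agnostic. Human-subject quantities (grand means, published t statistics,
retention percentages) depend on the human dataset and are exposed as
computations, not asserted as outcomes.
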