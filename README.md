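# timbrecapture

Auditory additional-singleton experiments in silico: stimulus synthesis,
trial-plan generation, synthetic observers, and the reaction-time analysis
that recovers a linear law of attentional capture by timbre.

## The problem

In the auditory additional-singleton paradigm, listeners judge the duration
of one target tone (shorter or longer than the rest) inside a rapid sequence
of five tones. On most trials one *singleton* tone differs from the
distractors on a task-irrelevant timbre dimension — brightness (spectral
centroid, SC) or roughness (50 Hz amplitude-modulation depth). Although the
singleton is useless for the task, it captures attention and slows
responses. Expressing the singleton's deviation in just-noticeable
differences (jnd: 5% of SC per brightness jnd, 0.10 of modulation depth per
roughness jnd), the capture cost follows a simple law:

```
E[ΔRT] = β · |d|        with d the deviation in jnd
```

— linear in the perceived deviation, symmetric in its sign, and additive
across the two timbre dimensions (`β_b·|d_b| + β_r·|d_r|`). This package is
for psychophysicists who want to generate the exact timbre-controlled
stimuli, pilot such designs, or validate the analysis pipeline by parameter
recovery on synthetic cohorts.

Four components, all importable from `timbrecapture`:

* **stimuli** — harmonic complexes (20 harmonics, weights `1/n^α`), the
  closed-form SC and its numerical inversion `α(SC)`, amplitude modulation,
  ramps, 5-tone sequences at a 230 ms inter-onset interval, WAV export, and
  spectral/envelope measurement oracles.
* **design** — jnd feature ladders (additive and compound), balanced
  seeded trial plans for the five standard designs (6×60 single-singleton;
  8×80 with four singleton variants), and trial→tone resolution.
* **observer** — a generative behavioral model: baseline RT ≈ 985 ms,
  truncated-normal trial noise, the linear/symmetric/additive capture cost,
  errors growing linearly with deviation, lapses, and a 3000 ms deadline.
* **analysis** — the standard cleaning (2-SD per-cell trim, <100 ms floor,
  no-answer removal, ≥40% error exclusion), condition summaries, LISAS,
  paired t-tests with Holm correction and Cohen's d, noncentral-t power
  (minimum n), and the RT-increase-vs-jnd regression.

## Worked example

```python
import timbrecapture as tc

population = tc.PopulationSpec(
    mean=tc.ObserverParams(slope_brightness_ms_per_jnd=14.0, sigma_rt_ms=150.0),
    mu_rt_sd_ms=140.0,
)
records = tc.run_experiment("exp2", seed=1, n_participants=20,
                            population=population)
result = tc.recover_capture_law(records, abscissa="jnd_brightness")
```

Running `python examples/05_recover_capture_law.py` (the same computation)
prints:

```
per-condition mean RT increases (across participants):
     1 jnd:   11.4 ms (SE 6.7)
     2 jnd:   34.0 ms (SE 6.9)
     5 jnd:   71.2 ms (SE 5.9)
    10 jnd:  145.2 ms (SE 7.0)

fitted law: RT increase = 14.48 ms/jnd x deviation + 0.3 ms
slope SE = 0.94, Pearson r = 0.868; generating value was 14.0 ms/jnd
```

The four singletons (SC 538, 563, 640, 768 Hz — 1, 2, 5 and 10 jnd above
the 512 Hz distractor) cost roughly 14 ms of response time per jnd, and the
pipeline recovers the slope the observers were generated with to well
within two standard errors. The other scripts in `examples/` walk through
stimulus synthesis, ladder construction, plan balance, the absent/present
summary table, and the statistics toolbox.

A thin CLI wraps the same calls:

```bash
timbrecapture synth exp2 --out tones/          # WAV tone bank + manifest
timbrecapture plan exp1 --seed 3 --out plan.csv
timbrecapture simulate exp2 --seed 3 -n 20 --out log.csv
timbrecapture analyze log.csv --out results/
timbrecapture reproduce exp2 --seed 3 --out results/ --no-audio
```

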