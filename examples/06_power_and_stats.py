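"""The statistics toolbox: power, paired tests, Holm, LISAS.

Shows the a-priori sample-size computation for the planned one-tailed
paired design, the paired t machinery with Cohen's d, the step-down Holm
adjustment for families of comparisons, and the LISAS speed-accuracy score.
"""

import numpy as np

import timbrecapture as tc

# sample size for a one-tailed paired t-test, d = 0.8, alpha = .05, power .8
n = tc.power_sample_size(0.8, alpha=0.05, power=0.8, tail="one-sided")
print(f"minimum sample size for d=0.8, alpha=.05, power=.8 (one-tailed): {n}")

# a paired contrast on made-up per-participant means
rng = np.random.default_rng(0)
baseline = rng.normal(1000, 120, 15)
with_singleton = baseline + rng.normal(130, 60, 15)
res = tc.paired_t(with_singleton, baseline, label="present - absent")
print(
    f"paired t({res.df}) = {res.t:.2f}, p = {res.p_raw:.1e}, "
    f"Cohen's d = {res.cohen_d:.2f}"
)

# Holm step-down over a family of four comparisons
raw = [0.005, 0.01, 0.03, 0.04]
print(f"Holm-adjusted {raw} -> {[round(float(p), 3) for p in tc.holm_correct(raw)]}")

# LISAS: mean correct RT plus an error penalty scaled by RT/error variability
rt_correct = rng.normal(1000, 100, 12)
errors = [1, 1, 1, 1] + [0] * 12
print(
    f"LISAS for a 16-trial cell (25% errors): "
    f"{tc.lisas(rt_correct, errors):.1f} ms "
    f"(mean correct RT {np.mean(rt_correct):.1f} ms)"
)
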