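"""Synthetic observers embodying the linear feature-driven capture law.

The generative model: on a trial with a singleton deviating by ``d_b``
brightness jnd and ``d_r`` roughness jnd from the distractors, the expected
response time grows by::

    capture_cost = slope_b * |d_b| + slope_r * |d_r|

i.e. the cost is linear in the perceived deviation, symmetric in its sign,
and additive across the two timbre dimensions.  Around that expectation,
single-trial RTs get truncated-normal noise; responses carry a baseline
error rate that grows linearly with the total deviation, occasional lapses
(random response, uniform RT), and a hard response deadline after which the
trial is recorded as unanswered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import ExperimentPlan, TrialSpec, plan_to_frame

__all__ = [
    "ObserverParams",
    "PopulationSpec",
    "TrialRecord",
    "capture_cost",
    "simulate_trial",
    "simulate_cohort",
]

RECORD_COLUMNS = [
    "participant", "experiment_id", "block", "trial", "target_kind",
    "target_pos", "condition", "singleton_pos", "jnd_brightness",
    "jnd_roughness", "response", "correct", "rt_ms",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative behavioral parameters for one participant.

    ``mu_rt_ms`` is the mean correct RT without a singleton (measured from
    target onset); ``sigma_rt_ms`` the trial-to-trial RT noise; the two
    slopes are the capture costs in ms per jnd.  ``base_error_rate`` plus
    ``error_capture_gain * total_jnd`` gives the error probability, and
    ``lapse_rate`` the probability of a random response with uniform RT.
    ``position_effect_ms`` (default off) adds a constant to RT when the
    singleton follows the target.
    """

    mu_rt_ms: float = 985.0
    sigma_rt_ms: float = 150.0
    slope_brightness_ms_per_jnd: float = 14.0
    slope_roughness_ms_per_jnd: float = 12.4
    additive_combination: bool = True
    base_error_rate: float = 0.162
    error_capture_gain: float = 0.0066
    lapse_rate: float = 0.02
    timeout_ms: float = 3000.0
    rt_floor_ms: float = 100.0
    position_effect_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "lapse_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.slope_brightness_ms_per_jnd < 0 or self.slope_roughness_ms_per_jnd < 0:
            raise ValueError("capture slopes must be >= 0")
        if not self.mu_rt_ms > self.rt_floor_ms:
            raise ValueError("baseline RT must exceed the floor")


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant variability around a set of mean parameters."""

    mean: ObserverParams = ObserverParams()
    mu_rt_sd_ms: float = 140.0
    slope_sd_ms_per_jnd: float = 0.0
    sigma_rt_sd_ms: float = 0.0

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        m = self.mean
        return replace(
            m,
            mu_rt_ms=max(
                m.rt_floor_ms + 1.0, m.mu_rt_ms + rng.normal(0, self.mu_rt_sd_ms)
            )
            if self.mu_rt_sd_ms > 0
            else m.mu_rt_ms,
            slope_brightness_ms_per_jnd=max(
                0.0,
                m.slope_brightness_ms_per_jnd + rng.normal(0, self.slope_sd_ms_per_jnd),
            )
            if self.slope_sd_ms_per_jnd > 0
            else m.slope_brightness_ms_per_jnd,
            slope_roughness_ms_per_jnd=max(
                0.0,
                m.slope_roughness_ms_per_jnd + rng.normal(0, self.slope_sd_ms_per_jnd),
            )
            if self.slope_sd_ms_per_jnd > 0
            else m.slope_roughness_ms_per_jnd,
            sigma_rt_ms=max(
                1.0, m.sigma_rt_ms + rng.normal(0, self.sigma_rt_sd_ms)
            )
            if self.sigma_rt_sd_ms > 0
            else m.sigma_rt_ms,
        )


@dataclass(frozen=True)
class TrialRecord:
    participant: int
    trial: TrialSpec
    response: str  # "short" | "long" | "none"
    correct: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if self.response != "none" and not self.rt_ms < 1e9:
            raise ValueError("answered trials need a finite RT")


def capture_cost(trial: TrialSpec, params: ObserverParams) -> float:
    """Expected RT increase in ms caused by the trial's singleton, if any."""
    s = trial.singleton
    if s is None:
        return 0.0
    cb = params.slope_brightness_ms_per_jnd * abs(s.jnd_brightness)
    cr = params.slope_roughness_ms_per_jnd * abs(s.jnd_roughness)
    return cb + cr if params.additive_combination else max(cb, cr)


def _other(kind: str) -> str:
    return "long" if kind == "short" else "short"


def simulate_trial(
    trial: TrialSpec, params: ObserverParams, rng: np.random.Generator
) -> TrialRecord:
    """Draw one trial outcome from the generative model."""
    if rng.random() < params.lapse_rate:
        response = "short" if rng.random() < 0.5 else "long"
        rt = float(rng.uniform(0.0, params.timeout_ms))
        return TrialRecord(
            0, trial, response, response == trial.target_kind, rt
        )
    rt = params.mu_rt_ms + capture_cost(trial, params)
    if params.position_effect_ms and trial.singleton_pos == "after":
        rt += params.position_effect_ms
    if params.sigma_rt_ms > 0:
        rt += rng.normal(0.0, params.sigma_rt_ms)
    rt = max(rt, 1.0)
    if rt >= params.timeout_ms:
        return TrialRecord(0, trial, "none", False, float("nan"))
    s = trial.singleton
    total_jnd = 0.0 if s is None else s.jnd_total
    p_err = min(1.0, params.base_error_rate + params.error_capture_gain * total_jnd)
    correct = rng.random() >= p_err
    response = trial.target_kind if correct else _other(trial.target_kind)
    return TrialRecord(0, trial, response, correct, float(rt))


def simulate_cohort(
    plan: ExperimentPlan,
    n_participants: int,
    population: Optional[PopulationSpec] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every participant running the full plan; one row per trial.

    Per-participant parameters are drawn from ``population`` with a
    participant-specific child RNG spawned from ``seed``, so results are
    reproducible and adding participants never perturbs earlier ones.
    The trial-level sampling is vectorized over the plan.
    """
    population = population or PopulationSpec()
    base = plan_to_frame(plan)
    cost_b = np.abs(base["jnd_brightness"].to_numpy())
    cost_r = np.abs(base["jnd_roughness"].to_numpy())
    after = (base["singleton_pos"] == "after").to_numpy()
    target_kind = base["target_kind"].to_numpy()
    n = len(base)

    frames = []
    seeds = np.random.SeedSequence(seed).spawn(n_participants)
    for pid, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        p = population.draw(rng)
        if p.additive_combination:
            cost = (
                p.slope_brightness_ms_per_jnd * cost_b
                + p.slope_roughness_ms_per_jnd * cost_r
            )
        else:
            cost = np.maximum(
                p.slope_brightness_ms_per_jnd * cost_b,
                p.slope_roughness_ms_per_jnd * cost_r,
            )
        rt = p.mu_rt_ms + cost + p.position_effect_ms * after
        if p.sigma_rt_ms > 0:
            rt = rt + rng.normal(0.0, p.sigma_rt_ms, size=n)
        rt = np.maximum(rt, 1.0)

        p_err = np.minimum(
            1.0, p.base_error_rate + p.error_capture_gain * (cost_b + cost_r)
        )
        correct = rng.random(n) >= p_err
        response = np.where(
            correct, target_kind, np.where(target_kind == "short", "long", "short")
        )

        lapse = rng.random(n) < p.lapse_rate
        lapse_resp = np.where(rng.random(n) < 0.5, "short", "long")
        lapse_rt = rng.uniform(0.0, p.timeout_ms, size=n)
        response = np.where(lapse, lapse_resp, response)
        rt = np.where(lapse, lapse_rt, rt)

        timeout = rt >= p.timeout_ms
        response = np.where(timeout, "none", response)
        rt = np.where(timeout, np.nan, rt)
        correct = (response == target_kind) & ~timeout

        df = base.copy()
        df.insert(0, "participant", pid)
        df["response"] = response
        df["correct"] = correct
        df["rt_ms"] = rt
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[RECORD_COLUMNS + [c for c in out.columns if c not in RECORD_COLUMNS]]
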