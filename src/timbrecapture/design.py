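"""Feature ladders and balanced trial plans for the five experiments.

A singleton's deviation from the distractor is expressed in just-noticeable
differences (jnd): 5% relative spectral-centroid change per brightness jnd
and 0.10 modulation depth per roughness jnd.  Ladders map jnd multipliers to
physical feature values; plans lay out blocks of trials with exact balance
quotas and a seeded shuffle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .stimuli import ToneSpec, solve_alpha_for_sc

Feature = Literal["brightness_sc", "roughness_depth"]

__all__ = [
    "FeatureLadder",
    "SingletonSpec",
    "TrialSpec",
    "ExperimentPlan",
    "build_ladder",
    "rounded_ladder",
    "generate_plan",
    "resolve_trial_tones",
    "plan_to_frame",
]


@dataclass(frozen=True)
class FeatureLadder:
    """A base feature value plus jnd-scaled steps defining singleton variants.

    ``additive`` mode steps linearly: ``base * (1 + jnd_fraction * k)`` for SC
    (or ``jnd_fraction * k`` absolute for depth, whose base is 0); ``compound``
    mode steps multiplicatively: ``base * (1 + jnd_fraction) ** k``.  Negative
    multipliers give downward steps.
    """

    feature: Feature
    base: float
    jnd_fraction: float
    multipliers: tuple[float, ...]
    mode: Literal["additive", "compound"] = "additive"

    def __post_init__(self) -> None:
        if len(self.multipliers) == 0:
            raise ValueError("multipliers must be non-empty")
        object.__setattr__(self, "multipliers", tuple(self.multipliers))


def build_ladder(ladder: FeatureLadder) -> list[float]:
    """Exact (unrounded) feature values for each jnd multiplier."""
    values = []
    for k in ladder.multipliers:
        if ladder.feature == "roughness_depth":
            # depth steps are absolute fractions of full modulation
            v = ladder.base + ladder.jnd_fraction * k
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"depth {v:.3f} for multiplier {k} outside [0, 1]"
                )
        elif ladder.mode == "additive":
            v = ladder.base * (1.0 + ladder.jnd_fraction * k)
        else:
            v = ladder.base * (1.0 + ladder.jnd_fraction) ** k
        if ladder.feature == "brightness_sc" and v <= 0:
            raise ValueError(f"non-physical SC {v:.3f} Hz for multiplier {k}")
        values.append(float(v))
    return values


def rounded_ladder(ladder: FeatureLadder) -> list[float]:
    """Ladder values rounded as reported: nearest Hz for SC, nearest 0.1 depth."""
    vals = build_ladder(ladder)
    if ladder.feature == "brightness_sc":
        return [float(round(v)) for v in vals]
    return [round(v, 1) for v in vals]


@dataclass(frozen=True)
class SingletonSpec:
    """Physical description of one singleton variant plus its jnd bookkeeping."""

    sc_hz: Optional[float] = None   # None -> distractor SC
    am_depth: float = 0.0
    jnd_brightness: float = 0.0
    jnd_roughness: float = 0.0
    level_db: float = 80.0

    @property
    def jnd_total(self) -> float:
        return abs(self.jnd_brightness) + abs(self.jnd_roughness)

    @property
    def label(self) -> str:
        parts = []
        if self.jnd_brightness:
            parts.append(f"b{self.jnd_brightness:+g}")
        if self.jnd_roughness:
            parts.append(f"r{self.jnd_roughness:+g}")
        return "".join(parts) or "sing"


@dataclass(frozen=True)
class TrialSpec:
    experiment_id: str
    block: int
    index: int
    target_kind: Literal["short", "long"]
    target_pos: Literal[3, 4]
    singleton: Optional[SingletonSpec]
    singleton_pos: Optional[Literal["before", "after"]]
    f0_jitter_hz: float = 0.0

    def __post_init__(self) -> None:
        if (self.singleton is None) != (self.singleton_pos is None):
            raise ValueError("singleton and singleton_pos must both be set or absent")
        if self.target_pos not in (3, 4):
            raise ValueError("target position must be 3 or 4")

    @property
    def condition(self) -> str:
        return "none" if self.singleton is None else self.singleton.label

    @property
    def singleton_slot(self) -> Optional[int]:
        if self.singleton is None:
            return None
        return self.target_pos + (1 if self.singleton_pos == "after" else -1)


@dataclass
class ExperimentPlan:
    experiment_id: str
    trials: list[TrialSpec]
    seed: int
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


def _exact_half(rng: np.random.Generator, n: int, items: Sequence) -> list:
    """A shuffled list of n items split exactly evenly between two labels."""
    if n % 2:
        raise ValueError(f"cannot split {n} trials exactly 50/50")
    out = [items[0]] * (n // 2) + [items[1]] * (n // 2)
    rng.shuffle(out)
    return out


def generate_plan(config, seed: int) -> ExperimentPlan:
    """Build the full, shuffled trial plan for one experiment.

    Every block satisfies its balance quotas exactly: targets 50/50 short/long
    and 50/50 position 3/4, the configured fraction of singleton trials split
    equally over the variants, and before/after 50/50 within each variant.
    The three assignments are shuffled independently with a seeded RNG and
    zipped, so the joint distribution over cells is randomized while all the
    marginal quotas hold in every block.  Identical (config, seed) pairs give
    identical plans.
    """
    from .configs import ExperimentConfig  # local import to avoid a cycle

    if not isinstance(config, ExperimentConfig):
        raise TypeError("config must be an ExperimentConfig")
    rng = np.random.default_rng(seed)
    n = config.block_size
    variants = config.singletons
    n_sing = round(n * config.singleton_fraction)
    if variants and n_sing % len(variants):
        raise ValueError(
            f"block size {n} with singleton fraction {config.singleton_fraction} "
            f"gives {n_sing} singleton trials, not divisible by "
            f"{len(variants)} variants"
        )
    quota = n_sing // len(variants) if variants else 0
    if quota % 2:
        raise ValueError(
            f"per-variant quota {quota} must be even for an exact "
            "before/after split"
        )

    trials: list[TrialSpec] = []
    for block in range(1, config.n_blocks + 1):
        conds: list[tuple[Optional[SingletonSpec], Optional[str]]] = []
        conds += [(None, None)] * (n - n_sing)
        for v in variants:
            conds += [(v, "before")] * (quota // 2) + [(v, "after")] * (quota // 2)
        rng.shuffle(conds)
        kinds = _exact_half(rng, n, ("short", "long"))
        positions = _exact_half(rng, n, (3, 4))
        jitter = rng.uniform(
            -config.f0_jitter_width_hz / 2, config.f0_jitter_width_hz / 2, size=n
        )
        for i in range(n):
            sing, ba = conds[i]
            trials.append(
                TrialSpec(
                    experiment_id=config.experiment_id,
                    block=block,
                    index=len(trials) + 1,
                    target_kind=kinds[i],
                    target_pos=positions[i],
                    singleton=sing,
                    singleton_pos=ba,
                    f0_jitter_hz=float(jitter[i]),
                )
            )
    return ExperimentPlan(
        experiment_id=config.experiment_id,
        trials=trials,
        seed=seed,
        config=config.to_dict(),
    )


def resolve_trial_tones(trial: TrialSpec, config) -> list[ToneSpec]:
    """Expand a planned trial into the 5 tone specifications of its sequence.

    All tones share the trial's jittered fundamental; the distractor exponent
    is solved so its SC equals the experiment's distractor SC at that f0, and
    a singleton specified by SC gets its own solved exponent.
    """
    f0 = config.f0_hz + trial.f0_jitter_hz
    alpha_dis = solve_alpha_for_sc(config.distractor_sc_hz, f0, config.n_harmonics)
    distractor = ToneSpec(
        f0=f0,
        alpha=alpha_dis,
        n_harmonics=config.n_harmonics,
        duration_ms=config.distractor_duration_ms,
        ramp_ms=config.ramp_ms,
        am_freq_hz=config.am_freq_hz,
        level_db=config.distractor_level_db,
    )
    dur = (
        config.target_long_ms if trial.target_kind == "long" else config.target_short_ms
    )
    target = distractor.replace(duration_ms=dur)
    tones = [distractor] * 5
    tones[trial.target_pos - 1] = target
    if trial.singleton is not None:
        s = trial.singleton
        alpha_s = (
            alpha_dis
            if s.sc_hz is None
            else solve_alpha_for_sc(s.sc_hz, f0, config.n_harmonics)
        )
        tones[trial.singleton_slot - 1] = distractor.replace(
            alpha=alpha_s, am_depth=s.am_depth, level_db=s.level_db
        )
    return tones


def plan_to_frame(plan: ExperimentPlan) -> pd.DataFrame:
    """One row per trial; singleton fields flattened, None where absent."""
    rows = []
    for t in plan.trials:
        s = t.singleton
        rows.append(
            {
                "experiment_id": t.experiment_id,
                "block": t.block,
                "trial": t.index,
                "target_kind": t.target_kind,
                "target_pos": t.target_pos,
                "condition": t.condition,
                "singleton_pos": t.singleton_pos,
                "singleton_sc_hz": None if s is None else s.sc_hz,
                "singleton_am_depth": None if s is None else s.am_depth,
                "jnd_brightness": 0.0 if s is None else s.jnd_brightness,
                "jnd_roughness": 0.0 if s is None else s.jnd_roughness,
                "f0_jitter_hz": t.f0_jitter_hz,
            }
        )
    return pd.DataFrame(rows)


def write_plan(plan: ExperimentPlan, path) -> None:
    """Serialize a plan to CSV with a JSON header comment carrying the seed."""
    header = json.dumps({"experiment_id": plan.experiment_id, "seed": plan.seed})
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        plan_to_frame(plan).to_csv(fh, index=False)
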