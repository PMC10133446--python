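"""Experiment configurations: timing constants, ladders, singleton variants.

The defaults live in ``data/experiments.yaml`` (one entry per experiment)
and are resolved here into :class:`ExperimentConfig` objects.  The nominal
fundamental frequency is not hard-coded: it is solved so that the reference
spectral slope (alpha = 3) yields the reference spectral centroid (512 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .design import FeatureLadder, SingletonSpec, build_ladder
from .stimuli import solve_alpha_for_sc

__all__ = ["ExperimentConfig", "load_experiment", "experiment_ids", "nominal_f0"]


def _load_yaml() -> dict:
    text = resources.files("timbrecapture").joinpath("data/experiments.yaml").read_text()
    return yaml.safe_load(text)


def nominal_f0(
    reference_sc_hz: float = 512.0,
    reference_alpha: float = 3.0,
    n_harmonics: int = 20,
) -> float:
    """Fundamental such that the reference exponent hits the reference SC."""
    from .stimuli import spectral_centroid

    ratio = spectral_centroid(reference_alpha, 1.0, n_harmonics)
    return reference_sc_hz / ratio


@dataclass
class ExperimentConfig:
    experiment_id: str
    n_blocks: int
    block_size: int
    singleton_fraction: float
    distractor_sc_hz: float
    singletons: list[SingletonSpec]
    f0_hz: float
    n_harmonics: int = 20
    f0_jitter_width_hz: float = 20.0
    distractor_duration_ms: float = 170.0
    target_short_ms: float = 120.0
    target_long_ms: float = 220.0
    ramp_ms: float = 5.0
    ioi_ms: float = 230.0
    timeout_ms: float = 3000.0
    am_freq_hz: float = 50.0
    distractor_level_db: float = 80.0
    extras: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_size

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "n_blocks": self.n_blocks,
            "block_size": self.block_size,
            "singleton_fraction": self.singleton_fraction,
            "distractor_sc_hz": self.distractor_sc_hz,
            "f0_hz": self.f0_hz,
            "n_harmonics": self.n_harmonics,
            "f0_jitter_width_hz": self.f0_jitter_width_hz,
            "ioi_ms": self.ioi_ms,
            "timeout_ms": self.timeout_ms,
            "singletons": [vars(s) for s in self.singletons],
        }


def _resolve_singletons(spec: dict, shared: dict) -> list[SingletonSpec]:
    if "literal" in spec:
        return [
            SingletonSpec(
                sc_hz=d.get("sc_hz"),
                am_depth=float(d.get("am_depth", 0.0)),
                jnd_brightness=float(d.get("jnd_brightness", 0.0)),
                jnd_roughness=float(d.get("jnd_roughness", 0.0)),
                level_db=float(d.get("level_db", 80.0)),
            )
            for d in spec["literal"]
        ]
    if "brightness_ladder" in spec:
        lad = spec["brightness_ladder"]
        ladder = FeatureLadder(
            "brightness_sc", lad["base"], lad["jnd_fraction"],
            tuple(lad["multipliers"]), lad["mode"],
        )
        levels = spec.get("levels_db", [80.0] * len(ladder.multipliers))
        return [
            SingletonSpec(sc_hz=v, jnd_brightness=float(k), level_db=float(lv))
            for v, k, lv in zip(build_ladder(ladder), ladder.multipliers, levels)
        ]
    if "roughness_ladder" in spec:
        lad = spec["roughness_ladder"]
        ladder = FeatureLadder(
            "roughness_depth", lad["base"], lad["jnd_fraction"],
            tuple(lad["multipliers"]), lad["mode"],
        )
        levels = spec.get("levels_db", [80.0] * len(ladder.multipliers))
        return [
            SingletonSpec(am_depth=v, jnd_roughness=float(k), level_db=float(lv))
            for v, k, lv in zip(build_ladder(ladder), ladder.multipliers, levels)
        ]
    if "cross" in spec:
        b = spec["cross"]["brightness"]
        r = spec["cross"]["roughness"]
        b_lad = FeatureLadder(
            "brightness_sc", b["base"], b["jnd_fraction"], tuple(b["multipliers"]), b["mode"]
        )
        r_lad = FeatureLadder(
            "roughness_depth", r["base"], r["jnd_fraction"], tuple(r["multipliers"]), r["mode"]
        )
        levels = spec.get("levels_db_by_brightness", {})
        out = []
        for sc, kb in zip(build_ladder(b_lad), b_lad.multipliers):
            for depth, kr in zip(build_ladder(r_lad), r_lad.multipliers):
                out.append(
                    SingletonSpec(
                        sc_hz=sc,
                        am_depth=depth,
                        jnd_brightness=float(kb),
                        jnd_roughness=float(kr),
                        level_db=float(levels.get(kb, 80.0)),
                    )
                )
        return out
    raise ValueError(f"unrecognized singleton specification: {sorted(spec)}")


def load_experiment(experiment_id: str, overrides: Optional[dict] = None) -> ExperimentConfig:
    """Load one experiment's configuration, optionally overriding fields."""
    data = _load_yaml()
    shared = data["shared"]
    try:
        exp = data["experiments"][experiment_id]
    except KeyError:
        raise KeyError(
            f"unknown experiment {experiment_id!r}; "
            f"available: {sorted(data['experiments'])}"
        ) from None
    f0 = nominal_f0(
        shared["reference_sc_hz"], shared["reference_alpha"], shared["n_harmonics"]
    )
    cfg = ExperimentConfig(
        experiment_id=experiment_id,
        n_blocks=exp["n_blocks"],
        block_size=exp["block_size"],
        singleton_fraction=exp["singleton_fraction"],
        distractor_sc_hz=exp["distractor_sc_hz"],
        singletons=_resolve_singletons(exp["singletons"], shared),
        f0_hz=f0,
        n_harmonics=shared["n_harmonics"],
        f0_jitter_width_hz=shared["f0_jitter_width_hz"],
        distractor_duration_ms=shared["distractor_duration_ms"],
        target_short_ms=shared["target_short_ms"],
        target_long_ms=shared["target_long_ms"],
        ramp_ms=shared["ramp_ms"],
        ioi_ms=shared["ioi_ms"],
        timeout_ms=shared["timeout_ms"],
        am_freq_hz=shared["am_freq_hz"],
        distractor_level_db=shared["distractor_level_db"],
    )
    for key, value in (overrides or {}).items():
        if not hasattr(cfg, key):
            raise AttributeError(f"no such config field: {key}")
        setattr(cfg, key, value)
    return cfg


def experiment_ids() -> list[str]:
    return sorted(_load_yaml()["experiments"])
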