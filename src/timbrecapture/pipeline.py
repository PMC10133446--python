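"""End-to-end drivers: simulate a cohort, run the analysis, recover the law.

``run_experiment`` chains plan generation and observer simulation;
``recover_capture_law`` runs cleaning, participant exclusion, condition
summaries and the jnd regression on a trial log; ``reproduce`` executes the
whole chain for one experiment and writes the tables, regression JSON and
figures to an output directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis
from .configs import ExperimentConfig, load_experiment
from .design import generate_plan, plan_to_frame, resolve_trial_tones
from .observer import ObserverParams, PopulationSpec, simulate_cohort

__all__ = [
    "RecoveryResult",
    "run_experiment",
    "recover_capture_law",
    "reproduce",
    "tone_bank",
]


@dataclass
class RecoveryResult:
    """Everything the capture-law recovery computes from one trial log."""

    regression: analysis.RegressionResult
    condition_means: pd.DataFrame          # per-condition mean increase + SE
    participant_points: pd.DataFrame       # per participant x condition increases
    cleaning: analysis.CleaningReport
    excluded: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "regression": asdict(self.regression),
            "condition_means": self.condition_means.to_dict(orient="records"),
            "cleaning": {
                "n_total": self.cleaning.n_total,
                "kept_fraction_all": self.cleaning.kept_fraction_all,
                "kept_fraction_correct": self.cleaning.kept_fraction_correct,
                "removed_by_rule": self.cleaning.removed_by_rule,
            },
            "excluded_participants": self.excluded,
        }


def run_experiment(
    experiment_id: str,
    seed: int,
    n_participants: int = 20,
    population: Optional[PopulationSpec] = None,
    config: Optional[ExperimentConfig] = None,
) -> pd.DataFrame:
    """Generate the plan for one experiment and simulate a cohort on it.

    The single seed drives both the plan shuffle and the observer draws
    (child streams), so a (experiment, seed, n) triple fully determines the
    trial log.
    """
    cfg = config or load_experiment(experiment_id)
    plan_seed, sim_seed = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    plan = generate_plan(cfg, int(plan_seed))
    return simulate_cohort(plan, n_participants, population, seed=int(sim_seed))


def recover_capture_law(
    records: pd.DataFrame,
    abscissa: str = "jnd_total",
    measure: str = "mean_rt_correct",
) -> RecoveryResult:
    """Clean a trial log and fit the RT-increase-vs-jnd line.

    ``abscissa`` selects the deviation axis: total (|brightness| +
    |roughness|), or one feature alone.  The regression is fit on the
    participant-level (jnd, increase) points; the per-condition table
    aggregates the same points into means with across-participant SEs.
    """
    surviving, dropped = analysis.exclude_participants(records)
    kept, report = analysis.clean(surviving)
    summaries = analysis.summarize_conditions(kept)
    increases = analysis.rt_increases(summaries, measure=measure)
    if abscissa not in increases.columns:
        raise KeyError(f"unknown abscissa {abscissa!r}")
    x = increases[abscissa].abs()
    reg = analysis.jnd_regression(list(zip(x, increases["increase_ms"])))
    cond = (
        increases.groupby("condition")
        .agg(
            jnd=(abscissa, lambda v: float(np.abs(v).iloc[0])),
            mean_increase_ms=("increase_ms", "mean"),
            se_increase_ms=("increase_ms", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
            n_participants=("participant", "nunique"),
        )
        .reset_index()
        .sort_values("jnd", ignore_index=True)
    )
    return RecoveryResult(
        regression=reg,
        condition_means=cond,
        participant_points=increases,
        cleaning=report,
        excluded=dropped,
    )


def tone_bank(config: ExperimentConfig) -> pd.DataFrame:
    """Manifest of the distinct tones an experiment needs, at nominal f0.

    One row per tone: the distractor, both targets, and each singleton
    variant, with solved exponent and closed-form SC.
    """
    from .stimuli import spectral_centroid, solve_alpha_for_sc

    f0 = config.f0_hz
    rows = []

    def add(tone_id, sc, depth, dur, level):
        alpha = solve_alpha_for_sc(sc, f0, config.n_harmonics)
        rows.append(
            {
                "tone_id": tone_id,
                "f0_hz": f0,
                "alpha": alpha,
                "sc_hz": spectral_centroid(alpha, f0, config.n_harmonics),
                "am_depth": depth,
                "duration_ms": dur,
                "level_db": level,
            }
        )

    add("distractor", config.distractor_sc_hz, 0.0,
        config.distractor_duration_ms, config.distractor_level_db)
    add("target_short", config.distractor_sc_hz, 0.0,
        config.target_short_ms, config.distractor_level_db)
    add("target_long", config.distractor_sc_hz, 0.0,
        config.target_long_ms, config.distractor_level_db)
    for s in config.singletons:
        add(
            f"singleton_{s.label}",
            s.sc_hz if s.sc_hz is not None else config.distractor_sc_hz,
            s.am_depth,
            config.distractor_duration_ms,
            s.level_db,
        )
    return pd.DataFrame(rows)


def _figure(result: RecoveryResult, experiment_id: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cond = result.condition_means
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        cond["jnd"], cond["mean_increase_ms"], yerr=cond["se_increase_ms"],
        fmt="o", capsize=3, label="condition means",
    )
    reg = result.regression
    xs = np.linspace(0, cond["jnd"].max() * 1.05, 50)
    ax.plot(
        xs, reg.intercept + reg.slope * xs, "-",
        label=f"fit: {reg.slope:.1f} ms/jnd",
    )
    ax.set_xlabel("singleton deviation (jnd)")
    ax.set_ylabel("RT increase (ms)")
    ax.set_title(f"{experiment_id}: capture cost vs perceived deviation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reproduce(
    experiment_id: str,
    seed: int,
    out_dir,
    n_participants: int = 20,
    population: Optional[PopulationSpec] = None,
    write_audio: bool = False,
    figures: bool = True,
) -> RecoveryResult:
    """Run plan -> simulate -> analyze for one experiment and write outputs.

    Writes the trial log, condition summary, regression JSON, cleaning
    report, tone-bank manifest (plus WAVs when ``write_audio``) and the
    RT-increase figure under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_experiment(experiment_id)
    records = run_experiment(
        experiment_id, seed, n_participants, population, config=cfg
    )
    records.to_csv(out / "trial_log.csv", index=False)

    result = recover_capture_law(records)
    result.condition_means.to_csv(out / "condition_means.csv", index=False)
    with open(out / "regression.json", "w") as fh:
        json.dump(
            {"experiment_id": experiment_id, "seed": seed, **result.to_json_dict()},
            fh, indent=2,
        )

    bank = tone_bank(cfg)
    bank.to_csv(out / "tone_bank.csv", index=False)
    if write_audio:
        from .stimuli import ToneSpec, synth_tone, write_wav

        for _, row in bank.iterrows():
            spec = ToneSpec(
                f0=row["f0_hz"], alpha=row["alpha"],
                n_harmonics=cfg.n_harmonics, duration_ms=row["duration_ms"],
                ramp_ms=cfg.ramp_ms, am_depth=row["am_depth"],
                am_freq_hz=cfg.am_freq_hz, level_db=row["level_db"],
            )
            write_wav(out / f"{row['tone_id']}.wav", synth_tone(spec))
    if figures:
        _figure(result, experiment_id, out / "rt_increase.png")
    return result
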