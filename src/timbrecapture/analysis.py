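"""Cleaning and statistics for additional-singleton trial logs.

The pipeline mirrors standard RT-experiment practice: per participant and
singleton condition, trials more than two standard deviations from the cell
mean are discarded, along with anticipations (< 100 ms) and unanswered
trials; participants with error rates at or above 40% are excluded; correct
RTs are summarized per condition; and the capture effect is quantified as
the per-participant RT increase (condition mean minus no-singleton mean),
regressed against the singleton's perceived deviation in jnd.

Speed-accuracy trade-offs are monitored with LISAS (the Linear Integrated
Speed Accuracy Score): mean correct RT plus the error proportion scaled by
the ratio of the RT and error-indicator standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CleaningReport",
    "TestResult",
    "RegressionResult",
    "clean",
    "exclude_participants",
    "lisas",
    "summarize_conditions",
    "rt_increases",
    "paired_t",
    "holm_correct",
    "power_sample_size",
    "jnd_regression",
    "position_effect",
    "surprise_effect",
]


@dataclass
class CleaningReport:
    n_total: int
    kept_fraction_all: float
    kept_fraction_correct: float
    removed_by_rule: dict = field(default_factory=dict)
    excluded_participants: list = field(default_factory=list)


@dataclass(frozen=True)
class TestResult:
    comparison: str
    t: float
    df: int
    p_raw: float
    cohen_d: float
    p_holm: Optional[float] = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float            # ms per jnd
    slope_se: float
    intercept: float
    pearson_r: float
    n_points: int
    degenerate: bool = False


def clean(
    records: pd.DataFrame,
    floor_ms: float = 100.0,
    k_sd: float = 2.0,
    min_cell: int = 3,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the outlier rules and report what was removed.

    Within each participant x condition cell, answered trials whose RT lies
    more than ``k_sd`` sample standard deviations from the cell mean are
    dropped; cells with fewer than ``min_cell`` answered trials are passed
    through untrimmed with a warning.  Trials faster than ``floor_ms`` and
    unanswered trials are always dropped.
    """
    df = records.copy()
    n_total = len(df)
    answered = df["response"].ne("none") & df["rt_ms"].notna()
    removed = {"no_answer": int((~answered).sum())}

    out_of_band = pd.Series(False, index=df.index)
    for (_, _), cell in df[answered].groupby(["participant", "condition"]):
        if len(cell) < min_cell:
            warnings.warn(
                f"cell with {len(cell)} answered trials passed through untrimmed",
                stacklevel=2,
            )
            continue
        mu = cell["rt_ms"].mean()
        sd = cell["rt_ms"].std(ddof=1)
        if sd > 0:
            out_of_band.loc[cell.index[(cell["rt_ms"] - mu).abs() > k_sd * sd]] = True
    removed["sd_rule"] = int(out_of_band.sum())

    too_fast = answered & df["rt_ms"].lt(floor_ms) & ~out_of_band
    removed["floor_rule"] = int(too_fast.sum())

    keep = answered & ~out_of_band & ~too_fast
    kept = df[keep].copy()
    report = CleaningReport(
        n_total=n_total,
        kept_fraction_all=len(kept) / n_total if n_total else 0.0,
        kept_fraction_correct=(
            float((kept["correct"]).sum()) / n_total if n_total else 0.0
        ),
        removed_by_rule=removed,
    )
    return kept, report


def exclude_participants(
    records: pd.DataFrame, max_error: float = 0.40
) -> tuple[pd.DataFrame, list[tuple[int, float]]]:
    """Drop participants whose overall error rate is not below ``max_error``.

    Unanswered trials count as errors.  Returns the surviving records and the
    (participant, error rate) pairs that were excluded.
    """
    err = 1.0 - records.groupby("participant")["correct"].mean()
    dropped = [(int(p), float(e)) for p, e in err.items() if e >= max_error]
    bad = {p for p, _ in dropped}
    return records[~records["participant"].isin(bad)].copy(), dropped


def lisas(rt_correct_ms: Sequence[float], errors: Sequence[int]) -> float:
    """Linear Integrated Speed Accuracy Score for one condition cell.

    ``rt_correct_ms`` are the correct-trial RTs; ``errors`` the 0/1 error
    indicators of all trials in the cell.  LISAS = mean correct RT +
    (SD_RT / SD_error) * error proportion (sample SDs); with no variability
    in errors it reduces to the mean RT.
    """
    rt = np.asarray(rt_correct_ms, dtype=float)
    err = np.asarray(errors, dtype=float)
    if rt.size == 0:
        raise ValueError("LISAS needs at least one correct trial")
    mean_rt = rt.mean()
    sd_rt = rt.std(ddof=1) if rt.size > 1 else 0.0
    sd_err = err.std(ddof=1) if err.size > 1 else 0.0
    if sd_err == 0:
        return float(mean_rt)
    return float(mean_rt + (sd_rt / sd_err) * err.mean())


def summarize_conditions(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition: mean correct RT, SD, error rate, LISAS.

    Expects cleaned records.  jnd columns are carried through for downstream
    regression.
    """
    rows = []
    for (pid, cond), cell in records.groupby(["participant", "condition"]):
        correct_rt = cell.loc[cell["correct"], "rt_ms"]
        errors = (~cell["correct"]).astype(int)
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "n_trials": len(cell),
                "mean_rt_correct": correct_rt.mean() if len(correct_rt) else np.nan,
                "sd_rt": correct_rt.std(ddof=1) if len(correct_rt) > 1 else 0.0,
                "error_rate": errors.mean(),
                "lisas": lisas(correct_rt, errors) if len(correct_rt) else np.nan,
                "jnd_brightness": cell["jnd_brightness"].iloc[0],
                "jnd_roughness": cell["jnd_roughness"].iloc[0],
            }
        )
    return pd.DataFrame(rows)


def rt_increases(summaries: pd.DataFrame, measure: str = "mean_rt_correct") -> pd.DataFrame:
    """Per-participant RT increase of each singleton condition over baseline.

    The baseline is the participant's no-singleton condition mean; the
    increase is computed within participant, matching how per-condition
    error bars are built (SE of these increases across participants).
    """
    base = summaries[summaries["condition"] == "none"].set_index("participant")[measure]
    sing = summaries[summaries["condition"] != "none"].copy()
    sing["increase_ms"] = sing[measure] - sing["participant"].map(base).to_numpy()
    sing["jnd_total"] = sing["jnd_brightness"].abs() + sing["jnd_roughness"].abs()
    return sing.dropna(subset=["increase_ms"])


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    tail: str = "two-sided",
    label: str = "",
) -> TestResult:
    """Paired t-test with Cohen's d = mean(diff) / SD(diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = a - b
    res = stats.ttest_rel(a, b, alternative={"two-sided": "two-sided",
                                             "greater": "greater",
                                             "less": "less"}[tail])
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else float("inf") * np.sign(diff.mean())
    return TestResult(
        comparison=label,
        t=float(res.statistic),
        df=int(a.size - 1),
        p_raw=float(res.pvalue),
        cohen_d=d,
    )


def holm_correct(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def power_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tail: str = "one-sided",
    n_max: int = 10_000,
) -> int:
    """Smallest n giving a paired/one-sample t-test the requested power.

    Exact noncentral-t scan: for each n the power is evaluated at
    noncentrality d*sqrt(n) against the alpha critical value, and the first
    n reaching the target is returned.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        ncp = d * np.sqrt(n)
        if tail == "one-sided":
            tcrit = stats.t.ppf(1 - alpha, df)
            achieved = 1 - stats.nct.cdf(tcrit, df, ncp)
        else:
            tcrit = stats.t.ppf(1 - alpha / 2, df)
            achieved = (1 - stats.nct.cdf(tcrit, df, ncp)) + stats.nct.cdf(
                -tcrit, df, ncp
            )
        if achieved >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches the requested power")


def jnd_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS fit of RT increase (ms) against perceived deviation (jnd).

    Returns slope, its standard error, intercept and Pearson r.  A constant
    ordinate makes r undefined; the result is then flagged degenerate with
    slope 0 and r reported as 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("regression needs at least 3 (jnd, increase) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return RegressionResult(0.0, 0.0, float(y.mean()), 0.0, len(x), degenerate=True)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_points=len(x),
    )


def _paired_means(records: pd.DataFrame, column: str, level_a, level_b):
    g = (
        records[records["correct"]]
        .groupby(["participant", column])["rt_ms"]
        .mean()
        .unstack(column)
    )
    g = g.dropna(subset=[level_a, level_b])
    return g[level_a].to_numpy(), g[level_b].to_numpy()


def position_effect(records: pd.DataFrame, tail: str = "two-sided") -> TestResult:
    """Paired t on correct RTs: singleton after vs before the target."""
    sing = records[records["condition"] != "none"]
    if sing["singleton_pos"].isna().all():
        raise ValueError("records carry no singleton position labels")
    after, before = _paired_means(sing, "singleton_pos", "after", "before")
    return paired_t(after, before, tail=tail, label="singleton after - before")


def surprise_effect(records: pd.DataFrame, tail: str = "two-sided") -> TestResult:
    """Paired t: singleton trials preceded by a no-singleton trial vs not.

    'Surprising' singleton trials follow one or more singleton-absent trials;
    'non-surprising' ones follow a singleton trial.  Trial order within
    participant follows the trial index.
    """
    df = records.sort_values(["participant", "trial"]).copy()
    prev_cond = df.groupby("participant")["condition"].shift(1)
    df["surprise"] = np.where(prev_cond == "none", "surprising", "non-surprising")
    df = df[(df["condition"] != "none") & prev_cond.notna()]
    a, b = _paired_means(df, "surprise", "surprising", "non-surprising")
    return paired_t(a, b, tail=tail, label="surprising - non-surprising")
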