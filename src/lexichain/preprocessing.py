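"""Trial exclusion and summarisation pipeline for the four-task battery.

The fixed pipeline order is:

1. participant gate — drop any participant below ``min_accuracy`` (default
   75%) in at least one task, judged on all of that task's trials before
   any trial-level filtering;
2. drop incorrect trials (tallied per task against all trials);
3. drop remaining correct trials faster than ``rt_floor_ms`` (strictly
   below 300 ms by default; tallied against remaining correct trials);
4. drop outliers more than ``outlier_k`` (default 2.5) sample standard
   deviations above or below the participant's mean, computed within each
   participant x task x response-type cell on the trials surviving steps
   2-3, in a single pass.

Summaries then give one mean RT per participant x task over retained
trials of the configured response type (yes by default), Table-style
group descriptives, and the across-participant z-scored matrix that feeds
correlation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .latent_model import TASKS

__all__ = [
    "PreprocessingConfig",
    "ExclusionLog",
    "exclude_participants",
    "filter_trials",
    "remove_outliers",
    "summarize_participants",
    "standardize",
]


@dataclass
class PreprocessingConfig:
    min_accuracy: float = 0.75
    rt_floor_ms: float = 300.0
    outlier_k: float = 2.5
    response_for_summary: str = "yes"

    def __post_init__(self) -> None:
        if not 0 < self.min_accuracy < 1:
            raise ValueError("min_accuracy must lie in (0, 1)")
        if self.rt_floor_ms <= 0:
            raise ValueError("rt_floor_ms must be positive")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.response_for_summary not in ("yes", "no"):
            raise ValueError("response_for_summary must be 'yes' or 'no'")


def _stage_counts(removed: pd.Series, total: pd.Series) -> dict:
    out = {}
    for task in TASKS:
        rem = int(removed.get(task, 0))
        tot = int(total.get(task, 0))
        out[task] = {
            "removed": rem,
            "total": tot,
            "pct": 100.0 * rem / tot if tot else 0.0,
        }
    return out


@dataclass
class ExclusionLog:
    """Bookkeeping of every exclusion stage.

    Stage percentages use the stated denominators: incorrect trials
    against all trials, fast trials against remaining correct trials,
    outliers against trials remaining after the first two steps.
    """

    participants_excluded: list[dict] = field(default_factory=list)
    incorrect: dict = field(default_factory=dict)
    fast: dict = field(default_factory=dict)
    outliers: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "ExclusionLog") -> "ExclusionLog":
        return ExclusionLog(
            participants_excluded=self.participants_excluded
            + other.participants_excluded,
            incorrect={**self.incorrect, **other.incorrect},
            fast={**self.fast, **other.fast},
            outliers={**self.outliers, **other.outliers},
            warnings=self.warnings + other.warnings,
        )

    def to_dict(self) -> dict:
        return {
            "participants_excluded": self.participants_excluded,
            "incorrect_trials": self.incorrect,
            "fast_trials": self.fast,
            "outlier_trials": self.outliers,
            "warnings": self.warnings,
        }


def exclude_participants(
    trials: pd.DataFrame, config: PreprocessingConfig
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop participants below ``min_accuracy`` in at least one task.

    Accuracy is correct/total over all of a task's trials, before any
    trial filtering; the boundary is inclusive (exactly ``min_accuracy``
    is retained).  A participant missing a task entirely raises.
    """
    log = ExclusionLog()
    task_counts = trials.groupby("participant_id", sort=True)["task"].agg(set)
    for pid, present in task_counts.items():
        missing = [t for t in TASKS if t not in present]
        if missing:
            raise ValueError(
                f"participant {pid!r} has no trials in task(s) {missing}"
            )
    acc = (
        trials.groupby(["participant_id", "task"], sort=True)["correct"]
        .mean()
        .unstack("task")
    )
    failing = acc.lt(config.min_accuracy)
    excluded_ids = failing.index[failing.any(axis=1)]
    for pid in excluded_ids:
        log.participants_excluded.append(
            {
                "participant_id": pid,
                "accuracies": {t: float(acc.loc[pid, t]) for t in TASKS},
                "failed_tasks": [t for t in TASKS if failing.loc[pid, t]],
            }
        )
    kept = trials[~trials["participant_id"].isin(excluded_ids)].reset_index(drop=True)
    return kept, log


def filter_trials(
    trials: pd.DataFrame, config: PreprocessingConfig
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove incorrect trials, then correct trials below the RT floor.

    The order is fixed: an incorrect fast trial counts only in the
    incorrect tally.  The floor is strict (a trial at exactly the floor is
    retained).
    """
    log = ExclusionLog()
    total = trials.groupby("task")["rt_ms"].size()
    incorrect = ~trials["correct"].astype(bool)
    log.incorrect = _stage_counts(
        trials[incorrect].groupby("task")["rt_ms"].size(), total
    )
    correct_trials = trials[~incorrect]
    remaining = correct_trials.groupby("task")["rt_ms"].size()
    fast = correct_trials["rt_ms"] < config.rt_floor_ms
    log.fast = _stage_counts(
        correct_trials[fast].groupby("task")["rt_ms"].size(), remaining
    )
    kept = correct_trials[~fast].reset_index(drop=True)
    return kept, log


def remove_outliers(
    trials: pd.DataFrame, config: PreprocessingConfig
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Single-pass removal of RTs beyond k sample SDs of their cell mean.

    Cells are participant x task x response-type; the mean and SD (n-1
    denominator) are computed on the trials given (i.e. after the earlier
    filters) and are not re-iterated after removal.  Cells with fewer than
    3 trials are left untouched with a warning.
    """
    log = ExclusionLog()
    total = trials.groupby("task")["rt_ms"].size()
    cells = trials.groupby(["participant_id", "task", "response"], sort=False)
    cell_mean = cells["rt_ms"].transform("mean")
    cell_sd = cells["rt_ms"].transform("std")
    cell_n = cells["rt_ms"].transform("size")
    small = cell_n < 3
    if small.any():
        for key in (
            trials[small]
            .groupby(["participant_id", "task", "response"], sort=True)
            .size()
            .index
        ):
            log.warnings.append(
                f"cell {key} has fewer than 3 trials; outlier step skipped"
            )
    deviation = (trials["rt_ms"] - cell_mean).abs()
    # absolute guard against float roundoff when the cell is (near-)constant
    tol = 1e-9 * np.maximum(1.0, cell_mean.abs())
    is_outlier = (deviation > config.outlier_k * cell_sd.fillna(0.0) + tol) & ~small
    log.outliers = _stage_counts(
        trials[is_outlier].groupby("task")["rt_ms"].size(), total
    )
    kept = trials[~is_outlier].reset_index(drop=True)
    return kept, log


def summarize_participants(
    trials: pd.DataFrame,
    config: PreprocessingConfig,
    raw_trials: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Per-participant task means plus group descriptives.

    ``trials`` must be fully filtered; ``raw_trials`` (post participant
    exclusion, pre trial filtering) supplies the error rates, which are
    defined before trial filtering.  Returns ``(summaries, descriptives,
    log)`` where ``summaries`` has one row per participant x task with the
    mean RT over retained trials of ``config.response_for_summary`` and
    ``descriptives`` is a per-task table of yes/no mean RT, trial-pooled
    standard error, and error percentages by stimulus type.
    """
    log = ExclusionLog()
    sel = trials[trials["response"] == config.response_for_summary]
    summaries = (
        sel.groupby(["participant_id", "task"], sort=True)["rt_ms"]
        .agg(mean_rt="mean", n_used="size")
        .reset_index()
    )
    # flag participants missing a cell for the summary response type
    pids = trials["participant_id"].unique()
    have = summaries.groupby("participant_id")["task"].nunique()
    for pid in pids:
        if have.get(pid, 0) < len(TASKS):
            log.warnings.append(
                f"participant {pid!r} has an empty {config.response_for_summary}-"
                "response cell after filtering; dropped from correlation input"
            )

    rows = []
    err_src = raw_trials if raw_trials is not None else trials
    for task in TASKS:
        t_task = trials[trials["task"] == task]
        row: dict = {"task": task}
        for resp in ("yes", "no"):
            rts = t_task.loc[t_task["response"] == resp, "rt_ms"]
            row[f"{resp}_mean_rt"] = float(rts.mean()) if len(rts) else float("nan")
            row[f"{resp}_se"] = (
                float(rts.std(ddof=1) / np.sqrt(len(rts))) if len(rts) > 1 else float("nan")
            )
            row[f"{resp}_n"] = int(len(rts))
        e_task = err_src[err_src["task"] == task]
        for resp, stim in (("yes", "target"), ("no", "foil")):
            cell = e_task[e_task["stimulus_class"] == stim]
            row[f"{resp}_error_pct"] = (
                100.0 * float((~cell["correct"].astype(bool)).mean())
                if len(cell)
                else float("nan")
            )
        rows.append(row)
    descriptives = pd.DataFrame(rows).set_index("task")
    return summaries, descriptives, log


def standardize(summaries: pd.DataFrame) -> pd.DataFrame:
    """Participant x task matrix of z-scored mean RTs.

    Within each task the across-participant mean is subtracted and the
    across-participant sample SD divides; participants missing any task
    are dropped (listwise).  Requires at least 3 complete participants and
    non-degenerate columns.
    """
    wide = summaries.pivot(index="participant_id", columns="task", values="mean_rt")
    missing = [t for t in TASKS if t not in wide.columns]
    if missing:
        raise ValueError(f"missing task column(s) {missing} in summaries")
    wide = wide[list(TASKS)].dropna()
    if len(wide) < 3:
        raise ValueError(
            f"need at least 3 complete participants to standardize, got {len(wide)}"
        )
    sd = wide.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"degenerate cohort: zero across-participant SD in {bad}")
    return (wide - wide.mean()) / sd
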