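"""End-to-end analysis: trials -> exclusions -> standardized matrix ->
correlation inference, organised as a model / results pair.

``CrossTaskModel`` wraps a trial-level table (real or simulated); its
``fit`` applies the exclusion pipeline and correlation inference and
returns a ``CrossTaskResults`` carrying the exclusion log, Table-style
descriptives, RT-ratio summaries, per-task RT distribution summaries, the
full correlation section, and a text ``summary()``.  ``run_recovery_study``
repeats simulate -> analyze over many cohorts to measure how often the
hierarchy's signature pattern (adjacent-level partial correlations
exceeding the non-adjacent one) is recovered at the study's sample size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .correlations import CrossTaskCorrelations, correlation_matrix
from .latent_model import (
    TASKS,
    TRIAL_COLUMNS,
    ExperimentDesign,
    LatentAbilityModel,
    simulate_experiment,
)
from .preprocessing import (
    ExclusionLog,
    PreprocessingConfig,
    exclude_participants,
    filter_trials,
    remove_outliers,
    standardize,
    summarize_participants,
)
from .random_walk import RandomWalkParams, rt_distribution_summary

__all__ = [
    "CrossTaskModel",
    "CrossTaskResults",
    "run_analysis",
    "run_recovery_study",
    "RecoveryStudyResults",
]

logger = logging.getLogger("lexichain")

_ADJACENT_PARTIALS = (("ADT", "LDT"), ("LDT", "GDT"))
_NONADJACENT_PARTIAL = ("ADT", "GDT")


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        problems.append(f"missing column(s): {missing}")
    else:
        bad_tasks = sorted(set(trials["task"].unique()) - set(TASKS))
        if bad_tasks:
            problems.append(f"unknown task label(s): {bad_tasks} (expected {list(TASKS)})")
        bad_stim = sorted(set(trials["stimulus_class"].unique()) - {"target", "foil"})
        if bad_stim:
            problems.append(f"stimulus_class must be 'target'/'foil', found {bad_stim}")
        bad_resp = sorted(set(trials["response"].unique()) - {"yes", "no"})
        if bad_resp:
            problems.append(f"response must be 'yes'/'no', found {bad_resp}")
        rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
        if rt.isna().any():
            problems.append("rt_ms contains non-numeric values")
        elif (rt <= 0).any():
            problems.append("rt_ms must be strictly positive")
    if problems:
        raise ValueError(
            "trial table failed schema validation:\n  - " + "\n  - ".join(problems)
        )
    out = trials.copy()
    out["correct"] = out["correct"].astype(bool)
    out["rt_ms"] = out["rt_ms"].astype(float)
    return out


class CrossTaskModel:
    """Cross-task correlation analysis of a four-task trial table.

    Parameters
    ----------
    trials : DataFrame
        Trial-level data with the fixed columns ``participant_id, task,
        trial_index, stimulus_class, response, correct, rt_ms``.
    preprocessing : PreprocessingConfig, optional
        Exclusion thresholds (75% accuracy gate, 300 ms floor, 2.5 SD
        outlier cut by default).
    comparison_method : str
        Dependent-correlation test, ``"steiger_z"`` or ``"williams_t"``.
    control_task : str
        Task whose shared decision component is partialled out (NRT).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        preprocessing: PreprocessingConfig | None = None,
        comparison_method: str = "steiger_z",
        control_task: str = "NRT",
        simulation_config: dict | None = None,
    ) -> None:
        self.trials = _validate_trials(trials)
        self.preprocessing = preprocessing or PreprocessingConfig()
        self.comparison_method = comparison_method
        self.control_task = control_task
        self.simulation_config = simulation_config

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "CrossTaskModel":
        """Build from a DataFrame, optionally renaming external columns
        via ``column_map`` ({external name: canonical name})."""
        if column_map:
            df = df.rename(columns=dict(column_map))
        return cls(df, **kwargs)

    @classmethod
    def from_csv(
        cls,
        path,
        column_map: Mapping[str, str] | None = None,
        sep: str = ",",
        **kwargs,
    ) -> "CrossTaskModel":
        return cls.from_dataframe(
            pd.read_csv(path, sep=sep), column_map=column_map, **kwargs
        )

    @classmethod
    def from_simulation(
        cls,
        model: LatentAbilityModel | None = None,
        design: ExperimentDesign | None = None,
        walk: RandomWalkParams | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "CrossTaskModel":
        """Simulate a cohort from the hierarchical generative model and
        wrap it for analysis."""
        model = model or LatentAbilityModel()
        design = design or ExperimentDesign()
        walk = walk or RandomWalkParams()
        trials = simulate_experiment(model, design, walk, seed)
        sim_cfg = {
            "seed": seed,
            "n_participants": design.n_participants,
            "trials_per_task": dict(design.trials_per_task),
            "walk": {
                "start": walk.start,
                "criterion": walk.criterion,
                "drift": walk.drift,
                "increment_sd": walk.increment_sd,
                "step_duration_ms": walk.step_duration_ms,
            },
        }
        return cls(trials, simulation_config=sim_cfg, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "CrossTaskResults":
        cfg = self.preprocessing
        logger.info("input: %d trials, %d participants",
                    len(self.trials), self.trials["participant_id"].nunique())
        trials, log_p = exclude_participants(self.trials, cfg)
        logger.info("participant gate: %d excluded", len(log_p.participants_excluded))
        filtered, log_f = filter_trials(trials, cfg)
        logger.info("trial filters: %d trials remain", len(filtered))
        retained, log_o = remove_outliers(filtered, cfg)
        logger.info("outlier step: %d trials retained", len(retained))
        log = log_p.merge(log_f).merge(log_o)
        for w in log.warnings:
            logger.warning("%s", w)

        summaries, descriptives, log_s = summarize_participants(
            retained, cfg, raw_trials=trials
        )
        log = log.merge(log_s)
        std = standardize(summaries)
        if len(std) < 4:
            raise ValueError(
                f"fewer than 4 retained participants ({len(std)}); "
                "correlation inference is not meaningful"
            )
        corr = correlation_matrix(
            std, control=self.control_task, method=self.comparison_method
        )

        resp = cfg.response_for_summary
        nrt_mean = float(descriptives.loc["NRT", f"{resp}_mean_rt"])
        ratios = {
            task: round(float(descriptives.loc[task, f"{resp}_mean_rt"]) / nrt_mean, 4)
            for task in TASKS
        }
        rt_summaries = {
            task: rt_distribution_summary(
                retained.loc[
                    (retained["task"] == task) & (retained["response"] == resp),
                    "rt_ms",
                ].to_numpy()
            )
            for task in TASKS
        }
        return CrossTaskResults(
            model=self,
            exclusions=log,
            descriptives=descriptives,
            rt_ratios=ratios,
            rt_summaries=rt_summaries,
            summaries=summaries,
            standardized=std,
            correlations=corr,
            n_participants=len(std),
        )


@dataclass
class CrossTaskResults:
    """Fitted analysis: exclusion log, descriptives, correlation section."""

    model: CrossTaskModel
    exclusions: ExclusionLog
    descriptives: pd.DataFrame
    rt_ratios: dict[str, float]
    rt_summaries: dict
    summaries: pd.DataFrame
    standardized: pd.DataFrame
    correlations: CrossTaskCorrelations
    n_participants: int
    version: str = field(default=__version__)

    def config_echo(self) -> dict:
        cfg = self.model.preprocessing
        echo = {
            "min_accuracy": cfg.min_accuracy,
            "rt_floor_ms": cfg.rt_floor_ms,
            "outlier_k": cfg.outlier_k,
            "response_for_summary": cfg.response_for_summary,
            "comparison_method": self.model.comparison_method,
            "control_task": self.model.control_task,
        }
        if self.model.simulation_config:
            echo["simulation"] = self.model.simulation_config
        return echo

    def to_dict(self) -> dict:
        desc = {
            task: {k: float(v) for k, v in self.descriptives.loc[task].items()}
            for task in self.descriptives.index
        }
        return {
            "version": self.version,
            "config": self.config_echo(),
            "n_participants": self.n_participants,
            "exclusions": self.exclusions.to_dict(),
            "descriptives": desc,
            "rt_ratios_vs_NRT": self.rt_ratios,
            "rt_distributions": {t: s.to_dict() for t, s in self.rt_summaries.items()},
            "correlations": self.correlations.to_dict(),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        lines = []
        lines.append("Cross-task RT correlation analysis")
        lines.append("=" * 58)
        lines.append(f"participants retained: {self.n_participants}"
                     f"   (excluded: {len(self.exclusions.participants_excluded)})")
        lines.append("")
        lines.append("Descriptives (correct responses)")
        lines.append(f"{'task':<6}{'yes RT':>10}{'(SE)':>8}{'no RT':>10}{'(SE)':>8}"
                     f"{'yes err%':>10}{'no err%':>9}")
        for task in TASKS:
            d = self.descriptives.loc[task]
            lines.append(
                f"{task:<6}{d['yes_mean_rt']:>10.0f}{d['yes_se']:>8.2f}"
                f"{d['no_mean_rt']:>10.0f}{d['no_se']:>8.2f}"
                f"{d['yes_error_pct']:>10.2f}{d['no_error_pct']:>9.2f}"
            )
        lines.append("")
        lines.append("Mean yes-RT ratios vs NRT: "
                     + ", ".join(f"{t} {self.rt_ratios[t]:.2f}" for t in TASKS))
        lines.append("")
        lines.append(f"Pairwise Pearson r (n = {self.correlations.n})")
        header = f"{'':<6}" + "".join(f"{t:>8}" for t in TASKS)
        lines.append(header)
        for t1 in TASKS:
            row = f"{t1:<6}" + "".join(
                f"{self.correlations.r_matrix.loc[t1, t2]:>8.3f}" for t2 in TASKS
            )
            lines.append(row)
        lines.append("")
        lines.append(f"Partial r controlling {self.correlations.control}:")
        for (a, b), res in self.correlations.partials.items():
            lines.append(
                f"  r({a},{b}|{self.correlations.control}) = {res.r_partial:.3f}"
                f"   p = {res.p:.4g}"
            )
        lines.append("")
        lines.append(f"Dependent-correlation comparisons ({self.correlations.method}):")
        for c in self.correlations.comparisons:
            lines.append(
                f"  r = {c.r_jk:.3f} vs {c.r_jh:.3f} (shared {c.shared}): "
                f"stat = {c.statistic:.3f}, p = {c.p:.4g}"
            )
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_analysis(
    trials: pd.DataFrame,
    preprocessing: PreprocessingConfig | None = None,
    **kwargs,
) -> CrossTaskResults:
    """Convenience wrapper: build the model and fit it."""
    return CrossTaskModel(trials, preprocessing=preprocessing, **kwargs).fit()


@dataclass
class RecoveryStudyResults:
    """Distribution of correlation estimates over simulated cohorts."""

    replicates: pd.DataFrame
    n_replicates: int
    alpha: float
    freq_adjacent_exceeds_nonadjacent: float
    freq_nonadjacent_nonsignificant: float

    def to_dict(self) -> dict:
        quantiles = self.replicates.quantile([0.05, 0.5, 0.95]).to_dict()
        return {
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "freq_adjacent_partials_exceed_nonadjacent": self.freq_adjacent_exceeds_nonadjacent,
            "freq_nonadjacent_partial_nonsignificant": self.freq_nonadjacent_nonsignificant,
            "replicate_quantiles": {
                col: {str(q): v for q, v in vals.items()}
                for col, vals in quantiles.items()
            },
        }

    def summary(self) -> str:
        return (
            f"parameter recovery over {self.n_replicates} simulated cohorts\n"
            f"  adjacent partials > non-adjacent partial: "
            f"{100 * self.freq_adjacent_exceeds_nonadjacent:.1f}% of replicates\n"
            f"  non-adjacent partial non-significant at alpha={self.alpha}: "
            f"{100 * self.freq_nonadjacent_nonsignificant:.1f}% of replicates"
        )


def run_recovery_study(
    model: LatentAbilityModel | None = None,
    design: ExperimentDesign | None = None,
    walk: RandomWalkParams | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    preprocessing: PreprocessingConfig | None = None,
) -> RecoveryStudyResults:
    """Simulate ``n_replicates`` cohorts and run the full pipeline on each.

    Records the six pairwise correlations and three partial correlations
    per replicate, the frequency with which both adjacent-level partials
    exceed the non-adjacent partial, and the frequency with which the
    non-adjacent partial is non-significant at ``alpha``.
    """
    if n_replicates < 50:
        raise ValueError("n_replicates must be at least 50")
    model = model or LatentAbilityModel()
    design = design or ExperimentDesign()
    walk = walk or RandomWalkParams()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)

    rows = []
    for rep, rep_seed in enumerate(seeds):
        res = CrossTaskModel(
            simulate_experiment(model, design, walk, int(rep_seed)),
            preprocessing=preprocessing,
        ).fit()
        row: dict = {"replicate": rep, "n": res.correlations.n}
        for (a, b), r in res.correlations.pairwise.items():
            row[f"r_{a}_{b}"] = r.r
        for (a, b), pr in res.correlations.partials.items():
            row[f"pr_{a}_{b}"] = pr.r_partial
            row[f"pr_{a}_{b}_p"] = pr.p
        rows.append(row)
    reps = pd.DataFrame(rows)

    adj1 = reps[f"pr_{_ADJACENT_PARTIALS[0][0]}_{_ADJACENT_PARTIALS[0][1]}"]
    adj2 = reps[f"pr_{_ADJACENT_PARTIALS[1][0]}_{_ADJACENT_PARTIALS[1][1]}"]
    nonadj = reps[f"pr_{_NONADJACENT_PARTIAL[0]}_{_NONADJACENT_PARTIAL[1]}"]
    nonadj_p = reps[f"pr_{_NONADJACENT_PARTIAL[0]}_{_NONADJACENT_PARTIAL[1]}_p"]
    freq_order = float(((adj1 > nonadj) & (adj2 > nonadj)).mean())
    freq_nonsig = float((nonadj_p > alpha).mean())
    return RecoveryStudyResults(
        replicates=reps,
        n_replicates=n_replicates,
        alpha=alpha,
        freq_adjacent_exceeds_nonadjacent=freq_order,
        freq_nonadjacent_nonsignificant=freq_nonsig,
    )
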