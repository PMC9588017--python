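"""Generative model of a four-task speeded binary-decision battery.

Participants are characterised by four standardised latent abilities: a
generic binary-decision ability ``d`` and three reading abilities at the
letter (``l``), word (``w``) and sentence (``s``) levels.  The reading
abilities form a Gaussian chain — ``w`` regresses on ``l`` and ``s`` on
``w`` (plus an optional direct letter-to-sentence path, zero by default,
encoding the hypothesis that letters influence sentences only through
words).  Each task's evidence-accumulation drift is the task's base drift
scaled by ``exp(sum of task weights x abilities)``; the exponential link
keeps drifts positive and yields right-skewed RT distributions across
participants.

Tasks
-----
NRT  animal / non-animal picture classification (decision only)
ADT  letter vs pseudo-letter (decision + letter)
LDT  word vs pseudoword (decision + letter + word)
GDT  grammatical vs ungrammatical sequence (decision + word + sentence)

The default base drifts are calibrated so that, with the default walk
(criterion 10, step 10 ms), mean correct RTs for an average participant
land near the empirical battery means (yes-responses about 536 / 499 /
613 / 1098 ms for NRT / ADT / LDT / GDT, with no-responses slower);
correctness is an independent Bernoulli overlay with task- and
stimulus-type-specific error rates, and a small fraction of trials are
anticipatory fast guesses below 300 ms so that downstream filtering is
exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .random_walk import RandomWalkParams, first_passage_times

__all__ = [
    "TASKS",
    "ABILITIES",
    "LatentAbilityModel",
    "ExperimentDesign",
    "TRIAL_COLUMNS",
    "sample_abilities",
    "task_drift",
    "simulate_experiment",
    "implied_task_rt_correlations",
]

TASKS: tuple[str, ...] = ("NRT", "ADT", "LDT", "GDT")
ABILITIES: tuple[str, ...] = ("d", "l", "w", "s")

#: fixed column order of the trial table (also the CSV header)
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "task",
    "trial_index",
    "stimulus_class",
    "response",
    "correct",
    "rt_ms",
)


def _default_task_weights() -> dict[str, dict[str, float]]:
    return {
        "NRT": {"d": 0.12},
        "ADT": {"d": 0.12, "l": 0.11},
        "LDT": {"d": 0.12, "l": 0.02, "w": 0.10},
        "GDT": {"d": 0.12, "w": 0.02, "s": 0.12},
    }


def _default_base_drift() -> dict[str, dict[str, float]]:
    # base drift = (barrier / target mean steps) * exp(var(eta)/2), i.e.
    # calibrated so the population-mean RT, not the median participant's,
    # sits near the target battery means.
    return {
        "NRT": {"yes": 0.1879, "no": 0.1815},
        "ADT": {"yes": 0.2031, "no": 0.1967},
        "LDT": {"yes": 0.1653, "no": 0.1462},
        "GDT": {"yes": 0.0925, "no": 0.0755},
    }


def _default_error_rate() -> dict[str, dict[str, float]]:
    return {
        "NRT": {"yes": 0.0248, "no": 0.0159},
        "ADT": {"yes": 0.0293, "no": 0.0159},
        "LDT": {"yes": 0.0404, "no": 0.0307},
        "GDT": {"yes": 0.0630, "no": 0.1640},
    }


@dataclass
class LatentAbilityModel:
    """Population model of participant abilities and task drifts.

    ``chain_lw`` and ``chain_ws`` are the standardized regression weights
    of word-on-letter and sentence-on-word ability; ``direct_ls`` is the
    direct letter-to-sentence path (default 0).  ``task_weights`` maps each
    task to the loadings of its log-drift on the four abilities.
    ``base_drift`` and ``error_rate`` are keyed by task and stimulus type
    ("yes" = target stimulus, "no" = foil).
    """

    ability_sd: Mapping[str, float] = field(
        default_factory=lambda: {a: 1.0 for a in ABILITIES}
    )
    chain_lw: float = 0.5
    chain_ws: float = 0.55
    direct_ls: float = 0.0
    task_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_task_weights
    )
    base_drift: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_base_drift
    )
    error_rate: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_error_rate
    )
    fast_guess_rate: float = 0.001
    fast_guess_range: tuple[float, float] = (150.0, 299.0)

    def __post_init__(self) -> None:
        for a in ABILITIES:
            if self.ability_sd.get(a, 1.0) <= 0:
                raise ValueError(f"ability_sd[{a!r}] must be positive")
        self.residual_var_w  # noqa: B018 - raises if invalid
        self.residual_var_s  # noqa: B018
        for task in TASKS:
            for resp in ("yes", "no"):
                bd = self.base_drift[task][resp]
                if bd <= 0:
                    raise ValueError(f"base_drift[{task}][{resp}] must be positive")
                er = self.error_rate[task][resp]
                if not 0 <= er < 1:
                    raise ValueError(f"error_rate[{task}][{resp}] must be in [0, 1)")
        if not 0 <= self.fast_guess_rate < 1:
            raise ValueError("fast_guess_rate must be in [0, 1)")
        lo, hi = self.fast_guess_range
        if not (0 < lo <= hi < 300):
            raise ValueError("fast_guess_range must lie in (0, 300) ms")

    @property
    def residual_var_w(self) -> float:
        v = 1.0 - self.chain_lw**2
        if v <= 0:
            raise ValueError(
                f"invalid parameterization: |chain_lw| = {abs(self.chain_lw)} >= 1 "
                "leaves no residual variance for unit-variance word ability"
            )
        return v

    @property
    def residual_var_s(self) -> float:
        v = 1.0 - (
            self.chain_ws**2
            + self.direct_ls**2
            + 2.0 * self.chain_ws * self.direct_ls * self.chain_lw
        )
        if v <= 0:
            raise ValueError(
                "invalid parameterization: chain_ws/direct_ls imply variance >= 1 "
                "for unit-variance sentence ability"
            )
        return v

    def weight_matrix(self) -> np.ndarray:
        """Task-by-ability loading matrix, rows ordered as TASKS."""
        w = np.zeros((len(TASKS), len(ABILITIES)))
        for i, task in enumerate(TASKS):
            for j, a in enumerate(ABILITIES):
                w[i, j] = self.task_weights.get(task, {}).get(a, 0.0)
        return w


@dataclass
class ExperimentDesign:
    """Trial-count layout of the battery and response deadline."""

    n_participants: int = 48
    trials_per_task: Mapping[str, int] = field(
        default_factory=lambda: {"NRT": 120, "ADT": 120, "LDT": 240, "GDT": 240}
    )
    yes_proportion: float = 0.5
    rt_cap_ms: float = 3000.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 < self.yes_proportion < 1:
            raise ValueError("yes_proportion must lie in (0, 1)")
        if self.rt_cap_ms <= 0:
            raise ValueError("rt_cap_ms must be positive")
        for task in TASKS:
            n = self.trials_per_task.get(task, 0)
            if n < 1:
                raise ValueError(f"trials_per_task[{task!r}] must be positive")
            n_yes = n * self.yes_proportion
            if abs(n_yes - round(n_yes)) > 1e-9:
                raise ValueError(
                    f"trials_per_task[{task!r}] = {n} does not split exactly "
                    f"at yes_proportion = {self.yes_proportion}"
                )

    @property
    def trials_per_participant(self) -> int:
        return sum(self.trials_per_task[t] for t in TASKS)


def sample_abilities(
    model: LatentAbilityModel, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` participant ability vectors (columns d, l, w, s).

    ``d`` is independent standard normal; ``l`` is standard normal; ``w``
    and ``s`` follow the chain regressions with residuals scaled so every
    ability has unit variance before the per-component ``ability_sd``
    scaling.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = rng.standard_normal(n)
    l = rng.standard_normal(n)
    w = model.chain_lw * l + math.sqrt(model.residual_var_w) * rng.standard_normal(n)
    s = (
        model.chain_ws * w
        + model.direct_ls * l
        + math.sqrt(model.residual_var_s) * rng.standard_normal(n)
    )
    out = pd.DataFrame({"d": d, "l": l, "w": w, "s": s})
    for a in ABILITIES:
        out[a] *= model.ability_sd.get(a, 1.0)
    return out


def task_drift(
    abilities: Mapping[str, float] | pd.DataFrame,
    model: LatentAbilityModel,
    task: str,
    response_type: str,
) -> float | np.ndarray:
    """Drift for one task and stimulus type given abilities.

    ``drift = base_drift[task][response_type] * exp(sum_k weight_k * a_k)``;
    the exponential link guarantees positivity.  Accepts a single ability
    mapping or a DataFrame of participants (vectorised).
    """
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}")
    base = model.base_drift[task][response_type]
    weights = model.task_weights.get(task, {})
    if isinstance(abilities, pd.DataFrame):
        eta = np.zeros(len(abilities))
        for a, wgt in weights.items():
            eta += wgt * abilities[a].to_numpy()
        return base * np.exp(eta)
    eta = sum(wgt * abilities[a] for a, wgt in weights.items())
    return base * math.exp(eta)


def simulate_experiment(
    model: LatentAbilityModel,
    design: ExperimentDesign,
    walk: RandomWalkParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate the full trial table of one cohort.

    For every participant x task x trial: the stimulus is a target with
    probability ``yes_proportion`` (exact split, order shuffled per
    participant and task), correctness is Bernoulli with the task- and
    stimulus-specific error rate, and the RT is a first-passage time of
    the random walk at the participant's drift for that cell.  Walks not
    absorbed before ``rt_cap_ms`` are recorded as timeouts at the cap and
    marked incorrect.  A ``fast_guess_rate`` fraction of trials instead
    get anticipatory RTs uniform in ``fast_guess_range``.  A fixed seed
    yields an identical table.
    """
    rng = np.random.default_rng(seed)
    n_p = design.n_participants
    abilities = sample_abilities(model, n_p, rng)

    frames = []
    cap_steps = design.rt_cap_ms / walk.step_duration_ms
    max_steps = min(walk.max_steps, int(math.ceil(cap_steps)))
    for task in TASKS:
        n_t = design.trials_per_task[task]
        n_yes = round(n_t * design.yes_proportion)
        template = np.zeros(n_t, dtype=bool)
        template[:n_yes] = True
        stim = rng.permuted(np.tile(template, (n_p, 1)), axis=1)  # (n_p, n_t)
        is_target = stim.ravel()

        err = np.where(
            is_target,
            model.error_rate[task]["yes"],
            model.error_rate[task]["no"],
        )
        correct = rng.random(n_p * n_t) >= err

        eta = np.zeros(n_p)
        for a, wgt in model.task_weights.get(task, {}).items():
            eta += wgt * abilities[a].to_numpy()
        scale = np.repeat(np.exp(eta), n_t)
        base = np.where(
            is_target,
            model.base_drift[task]["yes"],
            model.base_drift[task]["no"],
        )
        drifts = base * scale

        times, censored = first_passage_times(
            rng, drifts, walk.increment_sd, walk.barrier, max_steps
        )
        rt = times * walk.step_duration_ms
        # timeouts: no response before the deadline
        timeout = censored | (rt > design.rt_cap_ms)
        rt = np.where(timeout, design.rt_cap_ms, rt)
        correct = correct & ~timeout

        if model.fast_guess_rate > 0:
            guess = rng.random(n_p * n_t) < model.fast_guess_rate
            lo, hi = model.fast_guess_range
            rt = np.where(guess, rng.uniform(lo, hi, n_p * n_t), rt)

        response = np.where(is_target == correct, "yes", "no")
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(np.arange(1, n_p + 1), n_t),
                    "task": task,
                    "trial_index": np.tile(np.arange(n_t), n_p),
                    "stimulus_class": np.where(is_target, "target", "foil"),
                    "response": response,
                    "correct": correct,
                    "rt_ms": rt,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    task_order = pd.Categorical(trials["task"], categories=TASKS, ordered=True)
    trials = (
        trials.assign(task=task_order)
        .sort_values(["participant_id", "task", "trial_index"], kind="stable")
        .reset_index(drop=True)
    )
    trials["task"] = trials["task"].astype(str)
    return trials[list(TRIAL_COLUMNS)]


def implied_task_rt_correlations(
    model: LatentAbilityModel,
    walk: RandomWalkParams,
    oracle_n: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo oracle: correlation matrix of expected yes-RTs.

    Draws ``oracle_n`` ability vectors, maps each to its expected correct
    yes-response RT per task through the closed form
    ``(criterion - start) / drift * step_duration`` (no trial noise), and
    returns the 4x4 correlation matrix of those expected RTs.
    """
    if oracle_n < 1000:
        raise ValueError("oracle_n too small for a stable oracle")
    rng = np.random.default_rng(seed)
    abilities = sample_abilities(model, oracle_n, rng)
    a_mat = abilities[list(ABILITIES)].to_numpy()
    eta = a_mat @ model.weight_matrix().T  # (n, 4) task order = TASKS
    base = np.array([model.base_drift[t]["yes"] for t in TASKS])
    expected_rt = walk.barrier / (base * np.exp(eta)) * walk.step_duration_ms
    corr = np.corrcoef(expected_rt, rowvar=False)
    return pd.DataFrame(corr, index=list(TASKS), columns=list(TASKS))
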