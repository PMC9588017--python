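import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lexichain as lx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trials(cells, yes_proportion=0.5):
    """Build a trial table from (participant, task, rts, n_errors) cells.

    ``rts`` are the RTs of correct trials; errors are appended as foil
    trials answered "yes" at 600 ms.  Correct trials alternate
    target/foil so both response types are populated.
    """
    rows = []
    for pid, task, rts, n_err in cells:
        idx = 0
        for i, rt in enumerate(rts):
            target = i % 2 == 0 if yes_proportion else True
            rows.append(
                {
                    "participant_id": pid,
                    "task": task,
                    "trial_index": idx,
                    "stimulus_class": "target" if target else "foil",
                    "response": "yes" if target else "no",
                    "correct": True,
                    "rt_ms": float(rt),
                }
            )
            idx += 1
        for _ in range(n_err):
            rows.append(
                {
                    "participant_id": pid,
                    "task": task,
                    "trial_index": idx,
                    "stimulus_class": "foil",
                    "response": "yes",
                    "correct": False,
                    "rt_ms": 600.0,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def planted_cohort(mean_matrix, n_trials=6, jitter=None, seed=0):
    """Cohort whose participant x task correct-trial means are planted.

    ``mean_matrix`` is a DataFrame (participants x 4 tasks).  Without
    jitter every trial in a cell equals the planted mean (zero-variance
    cells, so no outlier removal occurs and summaries equal the plants
    exactly).
    """
    rng = np.random.default_rng(seed)
    cells = []
    for pid, row in mean_matrix.iterrows():
        for task in lx.TASKS:
            if jitter:
                rts = row[task] + rng.uniform(-jitter, jitter, n_trials)
                rts = rts - rts.mean() + row[task]
            else:
                rts = np.full(n_trials, float(row[task]))
            cells.append((pid, task, rts, 0))
    return make_trials(cells)


@pytest.fixture(scope="session")
def default_model():
    return lx.LatentAbilityModel()


@pytest.fixture(scope="session")
def default_walk():
    return lx.RandomWalkParams()


@pytest.fixture(scope="session")
def small_cohort(default_model, default_walk):
    """12-participant cohort with reduced trial counts, for pipeline tests."""
    design = lx.ExperimentDesign(
        n_participants=12,
        trials_per_task={"NRT": 40, "ADT": 40, "LDT": 60, "GDT": 60},
    )
    return lx.simulate_experiment(default_model, design, default_walk, seed=101)


@pytest.fixture(scope="session")
def full_cohort(default_model, default_walk):
    """Full-size default cohort (48 x 720 trials)."""
    return lx.simulate_experiment(
        default_model, lx.ExperimentDesign(), default_walk, seed=2024
    )
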