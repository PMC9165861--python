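"""Shared fixtures: scaled-down synthetic cohorts.

Cohort sizes and trial durations here are scaled down from the full
study design so the whole suite runs at desk scale; the skill templates
themselves are the generator defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import surgskill as sk
from surgskill.features_table import build_feature_table


def scaled_durations(task: str, novice: float, intermediate: float, expert: float):
    return {
        "novice": {task: novice},
        "intermediate": {task: intermediate},
        "expert": {task: expert},
    }


@pytest.fixture(scope="session")
def separated_cohort_table() -> pd.DataFrame:
    """Feature table for a strongly group-separated 8/8/8 cohort.

    One pegboard task, two muscles, one side, three trials; durations
    keep the novice > intermediate > expert completion-time ordering.
    """
    cfg = sk.CohortConfig(
        group_sizes={"novice": 8, "intermediate": 8, "expert": 8},
        tasks=("pegboard",),
        trials_per_task=3,
        muscles=("ECU", "deltoid"),
        sides=("left",),
        task_durations=scaled_durations("pegboard", 30.0, 25.0, 22.0),
        seed=11,
    )
    return build_feature_table(sk.generate_cohort(cfg))


@pytest.fixture(scope="session")
def ecu_planted_table() -> pd.DataFrame:
    """Six-muscle cohort where only the ECU carries group structure."""
    cfg = sk.CohortConfig(
        group_sizes={"novice": 6, "intermediate": 6, "expert": 6},
        tasks=("pegboard",),
        trials_per_task=2,
        muscles=sk.MUSCLES,
        sides=("left",),
        informative_muscles=("ECU",),
        task_durations=scaled_durations("pegboard", 22.0, 18.0, 15.0),
        seed=21,
    )
    return build_feature_table(sk.generate_cohort(cfg))


@pytest.fixture(scope="session")
def tiny_pipeline_config() -> "sk.PipelineConfig":
    """Minimal full-pipeline configuration (2 subjects/group, 1 muscle)."""
    cohort = sk.CohortConfig(
        group_sizes={"novice": 2, "intermediate": 2, "expert": 2},
        tasks=("pegboard",),
        trials_per_task=2,
        muscles=("ECU",),
        sides=("left",),
        task_durations=scaled_durations("pegboard", 14.0, 12.0, 10.0),
        seed=0,
    )
    return sk.PipelineConfig(
        cohort=cohort,
        selection_method="cfs",
        grouping="row",
        muscle_sets=(("ECU",),),
        seed=5,
    )


@pytest.fixture
def logistic_map_series() -> np.ndarray:
    """Fully chaotic logistic map x_{n+1} = 4 x (1 - x); Lyapunov ln 2."""
    x = np.empty(2000)
    x[0] = 0.3
    for i in range(1999):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x
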