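import numpy as np
import pandas as pd
import pytest

from amlbench import (
    Cohort,
    CohortConfig,
    PredictionSet,
    PredictorConfig,
    generate_cohort,
    simulate_predictor,
)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A quick 60-patient cohort with a reduced panel."""
    return generate_cohort(
        CohortConfig(n_patients=60, n_proteins=12, n_clinical=6, seed=11)
    )


@pytest.fixture(scope="session")
def test_cohort() -> Cohort:
    """A 100-patient cohort at the default panel size (a test set stand-in)."""
    return generate_cohort(CohortConfig(n_patients=100, seed=42))


@pytest.fixture(scope="session")
def sc1_population(test_cohort):
    """A graded population of SC1 submissions (team id encodes skill order)."""
    sets = []
    for i, skill in enumerate(np.linspace(0.1, 0.9, 9)):
        cfg = PredictorConfig(f"team_{i}", skill=float(skill), seed=100 + i)
        sets.append(
            simulate_predictor(test_cohort, test_cohort.truth, cfg, "SC1")
        )
    return sets


def make_sc1_set(team_id: str, ids, confidences) -> PredictionSet:
    frame = pd.DataFrame(
        {"confidence": np.asarray(confidences, dtype=float)},
        index=pd.Index(ids, name="patient_id"),
    )
    return PredictionSet(team_id, "SC1", frame)


def make_survival_set(team_id: str, subchallenge: str, ids, weeks) -> PredictionSet:
    frame = pd.DataFrame(
        {
            "confidence": np.full(len(ids), 0.5),
            "predicted_weeks": np.asarray(weeks, dtype=float),
        },
        index=pd.Index(ids, name="patient_id"),
    )
    return PredictionSet(team_id, subchallenge, frame)
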