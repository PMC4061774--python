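import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sigensemble as se

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> se.SyntheticCohort:
    cfg = se.SimulationConfig(
        n_patients=100, n_genes=60, signature_size=10, seed=11
    )
    return se.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def full_views(small_cohort):
    return se.render_pipeline_views(small_cohort, se.full_factorial_design())


@pytest.fixture(scope="session")
def cohort_signature(small_cohort) -> se.Signature:
    return se.Signature("hypoxia_like", tuple(small_cohort.signature_genes))


@pytest.fixture(scope="session")
def full_votes(full_views, cohort_signature):
    votes, score_vectors = se.classify_views(full_views, cohort_signature)
    return votes, score_vectors


def random_survival(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small random right-censored survival table for oracle tests."""
    time = rng.exponential(5.0, n).round(1) + 0.1  # rounding forces some ties
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"p{i:02d}" for i in range(n)], name="patient_id"),
    )
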