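import numpy as np
import pytest

from catchain.core_model import LearningModel, StationaryModel
from catchain.task_sim import (
    LearningCohortSpec,
    StationaryCohortSpec,
    simulate_cohort,
    simulate_stationary_phase,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def stationary_model():
    return StationaryModel.from_probs([0.8, 0.85, 0.9, 0.99])


@pytest.fixture(scope="session")
def learning_model():
    """Staggered-onset learner: later positions start learning later."""
    return LearningModel(s=(0.1, 0.1, 0.1), m=(4.0, 2.5, 0.5))


@pytest.fixture(scope="session")
def plateau_trials(stationary_model):
    return simulate_stationary_phase(stationary_model, 1000, seed=42)


@pytest.fixture(scope="session")
def small_human_cohort():
    """Five learners, 120 photographic trials each, with ground truth."""
    return simulate_cohort(5, LearningCohortSpec(), seed=7)


@pytest.fixture(scope="session")
def small_monkey_cohort():
    return simulate_cohort(6, StationaryCohortSpec(n_trials=600), seed=9)
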