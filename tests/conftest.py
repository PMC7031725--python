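import numpy as np
import pytest

from palsyflow.pipeline import extract_cohort_features
from palsyflow.simulator import SimulationConfig, build_synthetic_model, simulate_cohort


@pytest.fixture(scope="session")
def model():
    """A mid-size synthetic morphable model shared across tests."""
    return build_synthetic_model(n_vertices=1500, n_components=10, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort: 2 patients per grade, 20 frames, 160x160 frames."""
    return SimulationConfig(
        grade_counts=(2, 2, 2, 2, 2, 2),
        frames_per_patient=20,
        image_size=(160, 160),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-composition cohort (80 patients, 100 frames each)."""
    cohort = simulate_cohort(SimulationConfig(seed=1))
    extract_cohort_features(cohort)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
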