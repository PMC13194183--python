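import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from maware.cohort import default_calibration, generate_study
from maware.task_design import TaskGeometry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> TaskGeometry:
    return TaskGeometry()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def small_study():
    """Six-participant study without trajectories (fast psychometrics)."""
    return generate_study(
        calibration=default_calibration(n_participants=6),
        seed=11,
        include_trajectories=False,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
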