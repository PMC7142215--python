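import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinemodes as km

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def squat_gt():
    """Ground truth with three strong planted modes and mild noise."""
    spectrum = 606.0 * np.array([0.45, 0.25, 0.15])
    return km.make_ground_truth("squat", spectrum=spectrum, noise_sd=0.2, seed=101)


@pytest.fixture(scope="session")
def squat_trials(squat_gt):
    return km.simulate_cohort(squat_gt, p=24, seed=202)


@pytest.fixture(scope="session")
def squat_training(squat_trials):
    return km.prepare_cohort(squat_trials)


@pytest.fixture(scope="session")
def squat_model(squat_training):
    return km.KineticPCA(motion="squat").fit(squat_training.samples)


def make_triangle_trial(
    subject_id="T01",
    motion="squat",
    n=101,
    peak=50,
    forces=None,
    flexion_peak=110.0,
    closed_chain=True,
):
    """Raw trial with a triangular flexion profile peaking at ``peak``."""
    flexion = np.concatenate(
        [
            np.linspace(5.0, flexion_peak, peak + 1),
            np.linspace(flexion_peak, 5.0, n - peak)[1:],
        ]
    )
    if forces is None:
        forces = np.tile(np.sin(np.linspace(0, np.pi, n)), (6, 1))
    return km.KineticTrial(
        subject_id=subject_id,
        motion=motion,
        sample_rate=100.0,
        knee_flexion=flexion,
        forces=np.asarray(forces, dtype=float),
        closed_chain=closed_chain,
    )
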