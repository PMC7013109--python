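import numpy as np
import pytest

from gaitsim.gait_synth import SubjectProfile, TrialSpec, generate_subject


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(subject_id="S000", height=1.77, mass=72.3, seed=42)


@pytest.fixture(scope="session")
def walk_trial(profile):
    """One clean 1.4 m/s trial at 125 Hz: (segment series dict, truth)."""
    return generate_subject(profile, TrialSpec(speed=1.4, n_strides=4, rate=125.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_quaternion(rng, n=None):
    q = rng.standard_normal((n, 4) if n else 4)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
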