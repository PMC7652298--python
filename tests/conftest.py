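import numpy as np
import pytest

from roboreplay.robot import default_robot, planar_test_robot
from roboreplay.synthetic import ActivityParams, generate_activity
from roboreplay.transforms import RigidTransform, rotvec_to_matrix


@pytest.fixture(scope="session")
def robot():
    return default_robot()


@pytest.fixture(scope="session")
def planar_robot():
    return planar_test_robot()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tool():
    """Humerus tool frame: 0.10 m offset along the flange axis."""
    return RigidTransform(np.eye(3), np.array([0.0, 0.0, 0.10]))


def random_transform(rng: np.random.Generator) -> RigidTransform:
    return RigidTransform(
        rotvec_to_matrix(rng.uniform(-2.0, 2.0, size=3)),
        rng.uniform(-1.0, 1.0, size=3),
    )


@pytest.fixture(scope="session")
def slow_trial():
    """Slow small-amplitude jug-lift trial at a reduced rate (fast to solve)."""
    return generate_activity(ActivityParams("jug_lift", seed=3, rate=50.0, duration=4.0))
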