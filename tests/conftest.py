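import numpy as np
import pytest

from promorom.pipeline import specimen_from_joint
from promorom.synthetic_fixtures import JointSpec, ideal_joint_spec, make_joint


@pytest.fixture(scope="session")
def ideal_joint():
    """Ideal ball-and-socket: full-sphere articular head, no shaft."""
    return make_joint(ideal_joint_spec())


@pytest.fixture(scope="session")
def ideal_specimen(ideal_joint):
    return specimen_from_joint(ideal_joint, resolution=48, specimen_id="ideal")


@pytest.fixture(scope="session")
def realistic_joint():
    """Partial articular patch, shaft and tubercles: restricted ROM."""
    return make_joint(JointSpec(tubercle_height=2.5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
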