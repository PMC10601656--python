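import numpy as np
import pytest

from neurogait import skeleton as sk
from neurogait.muscle import MuscleSet
from neurogait.skeleton import SkeletonModel


@pytest.fixture(scope="session")
def model():
    """Default plant with contact and joint limits."""
    return SkeletonModel()


@pytest.fixture(scope="session")
def free_model():
    """Conservative variant: no contact, no joint limits."""
    return SkeletonModel(*sk.free_config())


@pytest.fixture(scope="session")
def muscles():
    return MuscleSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
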