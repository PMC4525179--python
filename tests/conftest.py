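import numpy as np
import pytest

from webstab import StrengthDistribution, bodysize_standin, generate_cascade


@pytest.fixture(scope="session")
def default_Z():
    return bodysize_standin("default")


@pytest.fixture(scope="session")
def point_mass_Z():
    return StrengthDistribution(-1.0, 0.5, family="point_mass")


@pytest.fixture(scope="session")
def complete_cascade_web():
    return generate_cascade(5, 1.0, seed=0)


@pytest.fixture(scope="session")
def three_cycle_K():
    K = np.zeros((3, 3), dtype=np.int8)
    K[0, 1] = K[1, 2] = K[2, 0] = 1
    return K
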