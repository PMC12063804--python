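import numpy as np
import pytest

from ctharmony.synthetic import generate_phantom, simulate_study
from ctharmony.types import default_groups


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(seed=0, shape=(32, 32, 24))


@pytest.fixture(scope="session")
def tiny_study():
    """Two protocol arms (3 and the reference 7), four test-retest scans."""
    groups = [g for g in default_groups() if g.group_id in (3, 7)]
    return simulate_study(seed=1, groups=groups, n_scans=4, shape=(24, 24, 16))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
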