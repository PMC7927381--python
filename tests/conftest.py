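import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _fixtures import cascade_fixture, random_matrix  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cascade_data():
    return cascade_fixture()


@pytest.fixture
def small_gm(rng):
    return random_matrix(rng, n_samples=10, n_snps=12, n_pops=2)
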