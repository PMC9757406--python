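import numpy as np
import pytest

from dmelm.dwt import build_feature_table
from dmelm.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def synthetic_table():
    """Feature table of the default synthetic dataset (100 segments/class)."""
    spec = SyntheticSpec(n_per_class=100, seed=0)
    return build_feature_table(generate_dataset(spec))


@pytest.fixture(scope="session")
def small_table():
    """A quick 20-per-class table for cheap structural tests."""
    spec = SyntheticSpec(n_per_class=20, n_samples=1024, seed=1)
    return build_feature_table(generate_dataset(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
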