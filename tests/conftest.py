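import numpy as np
import pytest

from aarspred import generate_dataset
from aarspred.synthetic import get_preset


@pytest.fixture(scope="session")
def stage1_data():
    """Stage-1 preset dataset (aaRS-like vs background), fixed seed."""
    return generate_dataset(get_preset("stage1", seed=11))


@pytest.fixture(scope="session")
def stage2_data():
    """Stage-2 preset dataset (class-1-like vs class-2-like), fixed seed."""
    return generate_dataset(get_preset("stage2", seed=11))


@pytest.fixture(scope="session")
def null_data():
    """Signal-free dataset for chance-level checks."""
    return generate_dataset(get_preset("null", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
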