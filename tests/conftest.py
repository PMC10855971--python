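import numpy as np
import pytest

from teanirs.dataset import SampleTable, split_sets
from teanirs.simulate import GeneratorConfig, generate_library


@pytest.fixture(scope="session")
def default_library() -> SampleTable:
    """The default 322-sample synthetic library at the package default seed."""
    return generate_library(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_split(default_library):
    """80/20 calibration/validation split of the default library."""
    return split_sets(default_library, 0.8, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
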