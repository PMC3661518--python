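import numpy as np
import pytest

from pmslt.interface import RunConfig, build_reference
from pmslt.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(synth_config):
    return generate_dataset(synth_config)


@pytest.fixture(scope="session")
def reference(dataset):
    return build_reference(dataset)


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
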