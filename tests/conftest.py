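import numpy as np
import pytest

from cutcoord.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_subjects=3, cycles_per_subject=4, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
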