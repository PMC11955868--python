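import numpy as np
import pytest

from vagusmap import ElectrodeCuff, SyntheticConfig, generate_cross_section


@pytest.fixture(scope="session")
def cuff() -> ElectrodeCuff:
    return ElectrodeCuff()


@pytest.fixture(scope="session")
def nerve():
    """One deterministic synthetic cross-section shared across tests."""
    return generate_cross_section(SyntheticConfig(seed=11), 0)[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
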