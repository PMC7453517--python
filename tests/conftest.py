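import numpy as np
import pytest

from cidecomp.simulate import SyntheticConfig, generate_wave


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Two-wave synthetic config at a size suitable for fast structural tests."""
    return SyntheticConfig(n={"1995": 800, "2014": 800}, seed=11)


@pytest.fixture(scope="session")
def small_wave(small_config):
    return generate_wave(small_config, "1995")


@pytest.fixture(scope="session")
def medium_wave():
    """One wave large enough for moment-convergence checks."""
    cfg = SyntheticConfig(n={"1995": 20_000, "2014": 10}, seed=5)
    return generate_wave(cfg, "1995")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
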