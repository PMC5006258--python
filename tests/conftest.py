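import numpy as np
import pytest

from bayesrar import TrialConfig


@pytest.fixture
def config() -> TrialConfig:
    return TrialConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_920)
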