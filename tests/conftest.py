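import numpy as np
import pytest

import tpgsim as t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bloom19():
    return t.default_bloom(19)


@pytest.fixture
def default_cfg():
    return t.GameConfig()
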