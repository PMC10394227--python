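import numpy as np
import pytest

from poselift import default_tree


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
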