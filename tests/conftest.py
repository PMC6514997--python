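import numpy as np
import pytest

import sifomri as sm


@pytest.fixture(scope="session")
def phantom64():
    return sm.shepp_logan(64)


@pytest.fixture(scope="session")
def phantom128():
    return sm.shepp_logan(128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
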