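import numpy as np
import pytest

from csmri import phantom as ph
from csmri import sensing as sn


@pytest.fixture(scope="session")
def head64():
    return ph.render_phantom(ph.default_head_spec(64))


@pytest.fixture(scope="session")
def head32():
    return ph.render_phantom(ph.default_head_spec(32))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def vd_mask16():
    return sn.generate_mask(16, "vd-random", 0.4, seed=1)
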