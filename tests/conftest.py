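import numpy as np
import pytest

from sootylung import phantom as ph


@pytest.fixture(scope="session")
def normal_phantom():
    return ph.generate_phantom(ph.spec_for_class("normal"), 11)


@pytest.fixture(scope="session")
def juxtapleural_phantom():
    return ph.generate_phantom(ph.spec_for_class("malignant", "juxtapleural"), 23)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
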