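import numpy as np
import pytest

import tfdimer as t


@pytest.fixture(scope="session")
def toy_protomer():
    return t.make_toy_protomer(11)


@pytest.fixture(scope="session")
def bundle():
    """Noise-free end-to-end synthetic study, shared across tests."""
    return t.make_full_fixture(11)


@pytest.fixture(scope="session")
def pre_config():
    return t.PREConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
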