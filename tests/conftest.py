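import numpy as np
import pytest

from ssnmrpipe import labeling, synthetic


@pytest.fixture(scope="session")
def helix20():
    return synthetic.make_helix_model(20, seed=42)


@pytest.fixture(scope="session")
def helix40():
    return synthetic.make_helix_model(40, seed=7)


@pytest.fixture(scope="session")
def uniform():
    return labeling.uniform_scheme()


@pytest.fixture(scope="session")
def shift_table20(helix20):
    return synthetic.make_shift_table(helix20, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
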