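import numpy as np
import pytest

from cdbsi.dictionary import build_default_dictionary
from cdbsi.fitting import build_design_matrix
from cdbsi.scheme import default_scheme


@pytest.fixture(scope="session")
def dictionary():
    return build_default_dictionary()


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def design(dictionary, scheme):
    return build_design_matrix(dictionary, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
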