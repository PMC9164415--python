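import numpy as np
import pytest

from frameshift_kit import load_matrix, standard_code


@pytest.fixture(scope="session")
def sgc():
    return standard_code()


@pytest.fixture(scope="session")
def gon250():
    return load_matrix("GON250")


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def pam250():
    return load_matrix("PAM250")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
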