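import numpy as np
import pytest

from phagescreen.alignment import default_matrix
from phagescreen.library_design import CodonDesign, builtin_template


@pytest.fixture(scope="session")
def loop_template():
    return builtin_template("loop")


@pytest.fixture(scope="session")
def side_template():
    return builtin_template("side")


@pytest.fixture(scope="session")
def codon_design():
    return CodonDesign()


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
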