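import numpy as np
import pytest

from semiflex.lattice import enumerate_angle_classes


@pytest.fixture(scope="session")
def bfm_angles():
    return enumerate_angle_classes("BFM")


@pytest.fixture(scope="session")
def lbfm_angles():
    return enumerate_angle_classes("LBFM")


@pytest.fixture(scope="session")
def sclm_angles():
    return enumerate_angle_classes("SCLM")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
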