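import numpy as np
import pytest

from murkit import MatchConfig, build_ladder, enumerate_ions
from murkit.table1 import load_table1, reproduce_table1


@pytest.fixture(scope="session")
def dap_ladder():
    return build_ladder("DAP")


@pytest.fixture(scope="session")
def lys_ladder():
    return build_ladder("Lys")


@pytest.fixture(scope="session")
def default_cfg():
    return MatchConfig()


@pytest.fixture(scope="session")
def dap_ions(dap_ladder, default_cfg):
    return enumerate_ions(dap_ladder, default_cfg)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_result():
    return reproduce_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
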