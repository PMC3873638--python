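import numpy as np
import pytest

from heteromf.params import DimensionalParams, nondimensionalize


@pytest.fixture(scope="session")
def p_table() -> DimensionalParams:
    """The CA3 pyramidal-cell parameter set (eta = 0, E_r = 0 mV)."""
    return DimensionalParams()


@pytest.fixture(scope="session")
def q_table(p_table):
    return nondimensionalize(p_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
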