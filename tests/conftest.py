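import numpy as np
import pytest

from stpnet.circuit import (
    reduced_circuit,
    reference_circuit,
    rs_fs_circuit,
    rs_lts_circuit,
)


@pytest.fixture(scope="session")
def reference():
    return reference_circuit()


@pytest.fixture(scope="session")
def rs_lts():
    """RS-LTS subcircuit with the figure-standard couplings (g_RL=35, g_LR=7.5)."""
    return rs_lts_circuit()


@pytest.fixture(scope="session")
def rs_fs():
    return rs_fs_circuit()


@pytest.fixture(scope="session")
def reduced():
    return reduced_circuit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
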