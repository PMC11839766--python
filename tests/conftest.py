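import numpy as np
import pytest

from stagescore import load_fixture

#: Printed MAP x STAGES cross-tabulation of the 58 validation sentences
#: (rows = MAP experts, columns = STAGES protocol, levels 1.0..6.5).
TABLE4 = np.array([
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [3, 2, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    [3, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 1, 0, 0, 2, 1, 3, 0, 0, 0, 0, 0],
    [0, 0, 0, 1, 2, 4, 14, 4, 0, 0, 0, 1],
    [0, 0, 0, 0, 0, 0, 3, 2, 0, 0, 0, 0],
    [0, 0, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0],
    [0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 2, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
])


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table3_pairs(table3):
    return table3.pairs()


@pytest.fixture(scope="session")
def table4_expected():
    return TABLE4
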