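import numpy as np
import pytest

from kvmech import get_scheme


@pytest.fixture(scope="session")
def scheme1():
    return get_scheme("scheme1_table1")


@pytest.fixture(scope="session")
def scheme2():
    return get_scheme("scheme2_table1")


@pytest.fixture(scope="session")
def scheme3_wt():
    return get_scheme("scheme3_WT_table2")


@pytest.fixture(scope="session")
def scheme3_ilt():
    return get_scheme("scheme3_ILT_table2")


@pytest.fixture(scope="session")
def scheme_hh_l4():
    return get_scheme("scheme1_table3_L4")


@pytest.fixture(scope="session")
def scheme_hh_l1():
    return get_scheme("scheme1_table3_L1")


@pytest.fixture(scope="session")
def all_schemes(scheme1, scheme2, scheme3_wt, scheme3_ilt, scheme_hh_l4,
                scheme_hh_l1):
    return [scheme1, scheme2, scheme3_wt, scheme3_ilt, scheme_hh_l4,
            scheme_hh_l1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20150213)
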