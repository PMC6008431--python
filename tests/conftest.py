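import warnings

import pytest

from idseq import ReadLayout, random_panel, random_plate


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        yield


@pytest.fixture(scope="session")
def layout():
    return ReadLayout()


@pytest.fixture(scope="session")
def small_panel():
    return random_panel(8, bc_len=10, seed=101)


@pytest.fixture(scope="session")
def small_plate():
    return random_plate(6, bc_len=10, seed=102)
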