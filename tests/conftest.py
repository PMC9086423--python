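import pytest

from hcc_cea.analysis import base_case
from hcc_cea.parameters import load_baseline


@pytest.fixture(scope="session")
def baseline():
    return load_baseline()


@pytest.fixture(scope="session")
def basecase_results(baseline):
    """(TACE result, FOLFOX-HAIC result, incremental comparison)."""
    return base_case(baseline)
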