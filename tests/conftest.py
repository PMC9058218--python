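import pytest

from radscav.fixtures import load_fixture


@pytest.fixture(scope="session")
def thb_benzene():
    return load_fixture("THB_benzene")


@pytest.fixture(scope="session")
def thp_benzene():
    return load_fixture("THP_benzene")


@pytest.fixture(scope="session")
def thb_water():
    return load_fixture("THB_water")


@pytest.fixture(scope="session")
def thp_water():
    return load_fixture("THP_water")
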