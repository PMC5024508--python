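import pytest

from simsmoke import default_effect_sizes, israel_fixture


@pytest.fixture(scope="session")
def params():
    return default_effect_sizes()


@pytest.fixture(scope="session")
def israel():
    """(CountryProfile, PolicyStatus) for the packaged Israel 2014 baseline."""
    return israel_fixture()


@pytest.fixture(scope="session")
def israel_profile(israel):
    return israel[0]


@pytest.fixture(scope="session")
def israel_status(israel):
    return israel[1]
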