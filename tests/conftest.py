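import pytest

from emoncavail.core import default_standards
from emoncavail.io import fixture_path, read_standards
from emoncavail.synth import generate, load_scenario


@pytest.fixture(scope="session")
def dh_scenario():
    return load_scenario(fixture_path("dh_scenario.yaml"))


@pytest.fixture(scope="session")
def dh_records(dh_scenario):
    return generate(dh_scenario)


@pytest.fixture(scope="session")
def mcwc_scenario():
    return load_scenario(fixture_path("mcwc_scenario.yaml"))


@pytest.fixture(scope="session")
def mcwc_records(mcwc_scenario):
    return generate(mcwc_scenario)


@pytest.fixture(scope="session")
def standards():
    return default_standards()


@pytest.fixture(scope="session")
def mcwc_standards():
    return read_standards(fixture_path("mcwc_standards.yaml"))
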