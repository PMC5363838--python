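import pytest

from tidemet.library import default_registry, paper_medium
from tidemet.network import default_network, paper_conversions
from tidemet.yields import EnergyContext


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def ctx(registry):
    return EnergyContext(dGf0_table=registry)


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def medium():
    return paper_medium()


@pytest.fixture(scope="session")
def observed():
    return paper_conversions()
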