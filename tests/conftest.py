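import pytest

from pksdesign.chemistry import simulate_cluster
from pksdesign.fixtures import fixture_collection


@pytest.fixture(scope="session")
def collection():
    return fixture_collection()


@pytest.fixture(scope="session")
def simulations(collection):
    return {c.id: simulate_cluster(c) for c in collection}
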