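import pytest

from ontoquery import Connector, LocalTransport, ServiceState, SetStore
from ontoquery import fixtures as fx


@pytest.fixture()
def go_regulation():
    return fx.go_regulation()


@pytest.fixture()
def cytomer_organs():
    return fx.cytomer_organs()


@pytest.fixture()
def endonet():
    return fx.endonet()


@pytest.fixture()
def tribolium():
    return fx.tribolium()


@pytest.fixture()
def store(tmp_path):
    return SetStore(tmp_path / "storage")


@pytest.fixture()
def service_state(store):
    """A service hosting all named fixtures plus the stored anatomy set."""
    state = ServiceState(store=store)
    for name in sorted(fx.NAMED_FIXTURES):
        state.add_ontology(fx.make_fixture(name))
    store.create_partition("endonet")
    store.put_list("endonet", "anatomy", list(fx.ENDONET_SET))
    return state


@pytest.fixture()
def connector(service_state):
    """Client wired to the service in-process (no sockets)."""
    return Connector(transport=LocalTransport(service_state))
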