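import pytest

from hoipy import build_senescence_fixture, materialize


@pytest.fixture(scope="session")
def doc():
    """The curated senescence course ontology (do not mutate; copy() first)."""
    return build_senescence_fixture()


@pytest.fixture(scope="session")
def graph(doc):
    """Materialized closure of the curated fixture."""
    return materialize(doc)
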