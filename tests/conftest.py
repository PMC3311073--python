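import pytest

from hyperpath.fixtures import (
    RandomNetworkSpec,
    make_toy_fixture,
    make_liquiritigenin_fixture,
    random_hypergraph,
)


@pytest.fixture
def toy():
    """Toy network with bootstrap/supplement structure: (H, source)."""
    return make_toy_fixture()


@pytest.fixture
def liquiritigenin():
    """Biosynthesis network with four minimal routes: (H, source, target)."""
    return make_liquiritigenin_fixture()


@pytest.fixture
def random_nets():
    """A callable yielding seeded random (H, source) pairs."""

    def make(seed, **kw):
        return random_hypergraph(RandomNetworkSpec(seed=seed, **kw))

    return make
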