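import pytest

from gofa.fixtures import (
    canonical_fixture,
    obsolete_augmented_fa,
    singleton_corpus,
)


@pytest.fixture(scope="session")
def fx():
    """The canonical worked fixture (graph, reference, FA, gold)."""
    return canonical_fixture()


@pytest.fixture(scope="session")
def graph(fx):
    return fx.graph


@pytest.fixture(scope="session")
def corpus():
    """Singleton-set corpus {C},{D},{E} used for the frozen IC values."""
    return singleton_corpus()


@pytest.fixture(scope="session")
def augmented():
    """FA carrying one dead obsolete annotation (obsolescence 1/3)."""
    return obsolete_augmented_fa()
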