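import numpy as np
import pytest

from lppi import Graph, fixture_a


@pytest.fixture(scope="session")
def fixture_a_data():
    """The canonical 300-node synthetic attributed network."""
    return fixture_a(seed=7)


@pytest.fixture()
def path4():
    """Path graph 0-1-2-3 with unit weights."""
    return Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture()
def triangle():
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


# small stage parameters for fast end-to-end tests (quality is irrelevant,
# plumbing is what is under test)
FAST = dict(
    t=4,
    gs_iters=2,
    dim=16,
    num_walks=3,
    walk_length=12,
    window=4,
    epochs=1,
    neg_samples=2,
)


@pytest.fixture()
def fast_params():
    return dict(FAST)
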