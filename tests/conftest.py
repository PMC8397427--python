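import networkx as nx
import pytest

from capsidperc import TilingSpec, capsid_network


@pytest.fixture(scope="session")
def t3_networks():
    """The three T=3 capsid bond networks (triangular, kite, rhombic)."""
    return {
        "triangular": capsid_network(TilingSpec("triangular", 1, 1)),
        "kite": capsid_network(TilingSpec("kite", 1, 1)),
        "rhombic": capsid_network(TilingSpec("rhombic", 1, 1)),
    }


@pytest.fixture(scope="session")
def hbv_network():
    """T=4 rhombic network: the architecture of the HBV capsid."""
    return capsid_network(TilingSpec("rhombic", 2, 0))


@pytest.fixture
def small_graphs():
    return {
        "c6": nx.cycle_graph(6),
        "p5": nx.path_graph(5),
        "s5": nx.star_graph(5),
        "k5": nx.complete_graph(5),
        "ico": nx.icosahedral_graph(),
    }
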