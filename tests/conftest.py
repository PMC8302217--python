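import networkx as nx
import pytest

from igpipe.species import default_ladder
from igpipe.synthetic_data import SimulationConfig, simulate_families


@pytest.fixture(scope="session")
def ladder():
    return default_ladder()


@pytest.fixture(scope="session")
def small_batch(ladder):
    """Sixty simulated families at the default duplication/loss rates."""
    cfg = SimulationConfig(n_families=60, duplication_rate=0.3, loss_rate=0.2)
    return simulate_families(ladder, cfg, 20240)


def true_orthology_graph(history):
    """Orthology graph straight from a simulated family's ground truth."""
    g = nx.Graph()
    for gene, sp in history.extant:
        g.add_node(gene, species=sp)
    for pair in history.ortholog_pairs:
        a, b = tuple(pair)
        g.add_edge(a, b)
    return g
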