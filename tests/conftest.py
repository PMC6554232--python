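import pytest
import scipy.sparse as sp

from netprop_gwas.network_io import PropagationNetwork, _build_network
from netprop_gwas.simulate import PlantedModuleSpec, generate


def network_from_edges(edges, declared_nodes=None):
    """Build a PropagationNetwork from {(u, v): weight} or [(u, v), ...]."""
    if not isinstance(edges, dict):
        edges = {e: 1.0 for e in edges}
    return _build_network(edges, declared_nodes=declared_nodes)


def random_network(rng, n, p=0.05):
    """Erdős–Rényi graph as a PropagationNetwork (isolates removed)."""
    names = [f"N{i:04d}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(names[i], names[j])] = 1.0
    if not edges:  # guarantee at least one edge
        edges[(names[0], names[1])] = 1.0
    return _build_network(edges)


@pytest.fixture
def two_node_network():
    """Single edge A–B."""
    return network_from_edges([("A", "B")])


@pytest.fixture
def path_network():
    """Path A–B–C."""
    return network_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def default_fixture_dir(tmp_path_factory):
    """One default synthetic study written to disk, shared per session."""
    out = tmp_path_factory.mktemp("study")
    paths = generate(PlantedModuleSpec(rng_seed=7), out)
    return paths
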