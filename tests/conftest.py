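import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def path3():
    """a - b - c."""
    g = nx.Graph([("a", "b"), ("b", "c")])
    g.graph["species"] = "toy"
    return g


@pytest.fixture
def triangle():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    g.graph["species"] = "toy"
    return g


@pytest.fixture
def path4():
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
    g.graph["species"] = "toy"
    return g


def random_connected_graph(n, p, seed):
    """Erdos-Renyi conditioned on connectivity (retry with shifted seed)."""
    for k in range(200):
        g = nx.gnp_random_graph(n, p, seed=seed + 1000 * k)
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            return nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g.nodes()})
    raise RuntimeError("no connected graph found")


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced two-species benchmark for fast structural tests."""
    from sinatra import synthgen

    spec = synthgen.BenchmarkSpec(
        n_nodes_source=220,
        n_nodes_target=140,
        n_complexes=18,
        n_pathways=8,
        n_sl=60,
        comut_n_pairs=300,
        seed=11,
    )
    return synthgen.generate_benchmark(spec)
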