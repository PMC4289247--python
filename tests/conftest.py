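import numpy as np
import pytest

from orthoclust.graph_core import SpeciesNetwork, build_multilayer


@pytest.fixture
def two_triangles() -> SpeciesNetwork:
    """Two disjoint triangles in one layer."""
    nodes = [f"g{i}" for i in range(6)]
    edges = [("g0", "g1"), ("g1", "g2"), ("g0", "g2"),
             ("g3", "g4"), ("g4", "g5"), ("g3", "g5")]
    return SpeciesNetwork.from_edges("sp", nodes, edges)


@pytest.fixture
def tiny_mln():
    """Two 3-clique layers joined by one one-to-one ortholog pair."""
    l1 = SpeciesNetwork.from_edges(
        "worm", ["w1", "w2", "w3"], [("w1", "w2"), ("w2", "w3"), ("w1", "w3")]
    )
    l2 = SpeciesNetwork.from_edges(
        "fly", ["f1", "f2", "f3"], [("f1", "f2"), ("f2", "f3"), ("f1", "f3")]
    )
    return build_multilayer([l1, l2], [("worm", "w1", "fly", "f1")])


def random_tiny_instance(rng, max_nodes_per_layer=5, p_ortho=0.2, signed=False):
    """Random two-layer instance with at least one edge per layer."""
    import itertools

    layers, names = [], []
    for li in range(2):
        n = int(rng.integers(3, max_nodes_per_layer + 1))
        sp = f"s{li + 1}"
        nodes = [f"{sp}n{i}" for i in range(n)]
        net = SpeciesNetwork(sp, nodes)
        pairs = list(itertools.combinations(range(n), 2))
        idx = rng.permutation(len(pairs))[: int(rng.integers(1, len(pairs) + 1))]
        for p in idx:
            i, j = pairs[p]
            sign = int(rng.choice([1, -1])) if signed else 1
            net.add_edge(nodes[i], nodes[j], sign)
        layers.append(net)
        names.append(nodes)
    rows = [
        ("s1", a, "s2", b)
        for a in names[0]
        for b in names[1]
        if rng.random() < p_ortho
    ]
    return build_multilayer(layers, rows)
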