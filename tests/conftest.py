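import pytest

from netcontrol import DirectedNetwork, fig3_network


@pytest.fixture
def chain():
    """Three-node chain a -> b -> c."""
    return DirectedNetwork(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def star():
    """One hub feeding two leaves: h -> t1, h -> t2."""
    return DirectedNetwork(edges=[("h", "t1"), ("h", "t2")])


@pytest.fixture(scope="session")
def fig3():
    """The published ERBB3/PI3K/AKT/MTOR worked example."""
    return fig3_network()


def enumerate_bounded_walks(edges, seeds, max_edges):
    """Independent oracle: all directed walks of <= max_edges edges between
    seed nodes (the two endpoints may coincide), as (nodes, edges) unions."""
    from collections import defaultdict

    out = defaultdict(list)
    for u, v in edges:
        out[u].append(v)
    nodes, kept = set(seeds), set()

    def extend(walk):
        if len(walk) > 1 and walk[-1] in seeds:
            nodes.update(walk)
            kept.update(zip(walk, walk[1:]))
        if len(walk) - 1 < max_edges:
            for nxt in out[walk[-1]]:
                extend(walk + [nxt])

    for s in seeds:
        extend([s])
    return nodes, kept
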