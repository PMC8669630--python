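import io

import pytest

import deathnet as dn


@pytest.fixture
def tiny_net() -> dn.MultilayerNetwork:
    """Three genes, two layers (PP: TP53-BAX, BAX-CASP3; A: TP53-BAX)."""
    net = dn.MultilayerNetwork()
    net.add_edge(dn.TypedEdge("TP53", "BAX", "PP"))
    net.add_edge(dn.TypedEdge("BAX", "CASP3", "PP"))
    net.add_edge(dn.TypedEdge("TP53", "BAX", "A"))
    return net


@pytest.fixture
def two_cliques() -> tuple[dn.MultilayerNetwork, dict[str, int]]:
    """Two disjoint 5-cliques in one PP layer, with the planted truth."""
    net = dn.MultilayerNetwork()
    truth: dict[str, int] = {}
    for block, prefix in enumerate(["A", "B"], start=1):
        members = [f"{prefix}{i}" for i in range(5)]
        for g in members:
            truth[g] = block
        for i in range(5):
            for j in range(i + 1, 5):
                net.add_edge(dn.TypedEdge(members[i], members[j], "PP"))
    return net, truth


@pytest.fixture
def toy_reference() -> dn.MultilayerNetwork:
    """Six genes, seven PP reference edges; used for hand-enumerated enrichment."""
    edges = [
        ("g1", "g2"),
        ("g1", "g3"),
        ("g2", "g3"),
        ("g3", "g4"),
        ("g4", "g5"),
        ("g5", "g6"),
        ("g4", "g6"),
    ]
    net = dn.MultilayerNetwork()
    for a, b in edges:
        net.add_edge(dn.TypedEdge(a, b, "PP"))
    return net


def read_lines(text: str):
    return io.StringIO(text)
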