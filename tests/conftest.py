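import pytest

from simpletigs import Graph, fixtures


@pytest.fixture(scope="session")
def g1() -> Graph:
    """Two-copy repeat graph: blocks a, r, b, c drawn as length-two paths."""
    return fixtures()["G1"]


@pytest.fixture(scope="session")
def g2() -> Graph:
    """Bubble graph: shared flanks a, c around divergent arms b, d."""
    return fixtures()["G2"]


def node_names(g: Graph, walk) -> tuple:
    return tuple(g.node_payload(v) for v in walk.nodes)


def by_name(g: Graph) -> dict:
    return {g.node_payload(v): v for v in g.nodes}
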