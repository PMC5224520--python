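import networkx as nx
import pytest

from shortloops import InteractionNetwork


def from_nx(g) -> InteractionNetwork:
    return InteractionNetwork.from_networkx(g)


def er_net(n: int, p: float, seed: int) -> InteractionNetwork:
    return from_nx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def triangle() -> InteractionNetwork:
    return InteractionNetwork([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def k4() -> InteractionNetwork:
    return from_nx(nx.complete_graph(["a", "b", "c", "d"]))


@pytest.fixture
def k5() -> InteractionNetwork:
    return from_nx(nx.complete_graph(5))


@pytest.fixture
def c6() -> InteractionNetwork:
    return from_nx(nx.cycle_graph(6))


@pytest.fixture
def petersen() -> InteractionNetwork:
    return from_nx(nx.petersen_graph())


@pytest.fixture
def star3() -> InteractionNetwork:
    """K_{1,3}: hub h with leaves x, y, z."""
    return InteractionNetwork([("h", "x"), ("h", "y"), ("h", "z")])


@pytest.fixture
def path3() -> InteractionNetwork:
    return InteractionNetwork([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def mini_ontology(tmp_path_factory):
    from shortloops.synth import write_obo

    path = tmp_path_factory.mktemp("onto") / "mini.obo"
    write_obo(path, n_modules=4, terms_per_module=6, background_terms=5)
    return path
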