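import networkx as nx
import pytest
from hypothesis import settings

from cnvmirnet.regnet import BipartiteNetwork, Evidence, InteractionEdge
from cnvmirnet.synthgen import fixture_small

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def predicted(mirna: str, gene: str) -> InteractionEdge:
    return InteractionEdge(mirna, gene, Evidence.PREDICTED)


def make_network(edge_pairs, extra_mirnas=(), extra_genes=()) -> BipartiteNetwork:
    """Build a BipartiteNetwork from (mirna, gene) pairs."""
    edges = {(m, g): predicted(m, g) for m, g in edge_pairs}
    mirnas = {m for m, _ in edge_pairs} | set(extra_mirnas)
    genes = {g for _, g in edge_pairs} | set(extra_genes)
    return BipartiteNetwork(mirnas, genes, edges)


def random_bipartite(seed: int, max_mirnas: int = 8, max_genes: int = 22) -> BipartiteNetwork:
    """Seeded random bipartite network (possibly disconnected, <= 30 nodes)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(2, max_mirnas + 1))
    n2 = int(rng.integers(3, max_genes + 1))
    p = float(rng.uniform(0.05, 0.35))
    graph = nx.bipartite.random_graph(n1, n2, p, seed=int(rng.integers(2**31)))
    mirnas = {f"m{v}" for v in range(n1)}
    genes = {f"g{v - n1}" for v in range(n1, n1 + n2)}
    pairs = [(f"m{u}", f"g{v - n1}") if u < n1 else (f"m{v}", f"g{u - n1}")
             for u, v in graph.edges]
    return make_network(pairs, extra_mirnas=mirnas, extra_genes=genes)


@pytest.fixture
def small_fixture():
    return fixture_small()


@pytest.fixture
def star_network():
    """K1,5 with the hub on the miRNA side."""
    return make_network([("hub", f"g{i}") for i in range(5)])


@pytest.fixture
def path_network():
    """Path a-b-c with b the miRNA."""
    return make_network([("b", "a"), ("b", "c")])
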