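import networkx as nx
import numpy as np
import pytest

from diffnet.synth import SyntheticSpec, gen_expression, gen_interactome


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def scenario_graph(default_spec):
    """Interactome + truth for the default planted scenario."""
    inter, truth = gen_interactome(default_spec)
    return inter, truth


@pytest.fixture(scope="session")
def expression_truth(default_spec):
    return gen_expression(default_spec)


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge c-d."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"),
                      ("c", "d")])
    return g


def brute_force_node_betweenness(g: nx.Graph) -> dict:
    """Path-enumeration betweenness oracle (raw pair-count convention):
    for every unordered pair, enumerate all shortest paths by BFS and credit
    each interior node with its fraction."""
    nodes = sorted(g)
    bw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = list(nx.all_shortest_paths(g, s, t)) if nx.has_path(g, s, t) else []
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bw[v] += 1.0 / len(paths)
    return bw


def brute_force_edge_betweenness(g: nx.Graph) -> dict:
    bw = {tuple(sorted(e)): 0.0 for e in g.edges()}
    nodes = sorted(g)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for u, v in zip(path, path[1:]):
                    bw[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return bw


def block_abundance(seed: int, noise: float = 0.2, n_blocks: int = 3,
                    genes_per_block: int = 10, samples_per_block: int = 5) -> np.ndarray:
    """Planted block-diagonal abundance matrix with uniform noise."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n_blocks * genes_per_block, n_blocks * samples_per_block))
    for b in range(n_blocks):
        X[b * genes_per_block:(b + 1) * genes_per_block,
          b * samples_per_block:(b + 1) * samples_per_block] = 1.0
    return X + rng.uniform(0, noise, X.shape)
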