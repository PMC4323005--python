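"""Node centrality and bottleneck/hub ranking.

Bottlenecks are the nodes with the highest betweenness centrality — they sit
on many shortest paths, so their removal fragments the network; hubs are
nodes of unusually high degree. Betweenness uses Brandes' algorithm over
unweighted shortest paths, reported in both the raw pair-count convention
(sum over unordered pairs of the fraction of shortest paths crossing the
node) and normalized by (n-1)(n-2)/2.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def node_betweenness(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Betweenness centrality of every node (Brandes accumulation)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.betweenness_centrality(g, normalized=normalized)


def node_degree(g: nx.Graph) -> dict[str, int]:
    """Undirected degree; parallel edges count once (simple-graph view)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    simple = nx.Graph(g)
    return dict(simple.degree())


def rank_bottlenecks_hubs(
    g: nx.Graph,
    top_n_bottlenecks: int = 18,
    hub_quantile: float = 0.9,
    hub_min_degree: int | None = None,
) -> pd.DataFrame:
    """Centrality table: betweenness (raw + normalized), degree, rank, and
    bottleneck / hub flags.

    Nodes are ranked by raw betweenness descending (ties: higher degree,
    then symbol order); the top ``top_n_bottlenecks`` are flagged as
    bottlenecks. Hubs have degree at or above the ``hub_quantile`` empirical
    quantile of the degree distribution (or an absolute ``hub_min_degree``).
    """
    n = g.number_of_nodes()
    if top_n_bottlenecks > n:
        raise ValueError(f"top_n_bottlenecks={top_n_bottlenecks} exceeds {n} nodes")
    raw = node_betweenness(g, normalized=False)
    norm = node_betweenness(g, normalized=True)
    deg = node_degree(g)
    order = sorted(raw, key=lambda v: (-raw[v], -deg[v], v))
    degrees = np.array([deg[v] for v in order])
    if hub_min_degree is None:
        hub_thresh = float(np.quantile(degrees, hub_quantile)) if n else 0.0
    else:
        hub_thresh = float(hub_min_degree)
    df = pd.DataFrame(
        {
            "node": order,
            "degree": [deg[v] for v in order],
            "betweenness_raw": [raw[v] for v in order],
            "betweenness_norm": [norm[v] for v in order],
            "rank": np.arange(1, n + 1),
        }
    )
    df["is_bottleneck"] = df["rank"] <= top_n_bottlenecks
    df["is_hub"] = df["degree"] >= hub_thresh
    return df.set_index("node")
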