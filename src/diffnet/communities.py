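"""Edge-betweenness (Girvan-Newman) community detection.

Modules are found by iteratively removing the edge with the highest
edge-betweenness (recomputed after every removal, raw pair-count
convention). Each removal that splits a component yields a candidate
partition; the cut is chosen either at a requested module count or at the
partition maximizing Newman-Girvan modularity on the original graph.
Ties in edge-betweenness are broken toward the lexicographically smallest
edge (by sorted endpoints) so the dendrogram is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

_TIE_TOL = 1e-9


@dataclass
class ModulePartition:
    module_of_node: dict[str, int]
    n_modules: int
    removals: list[tuple[str, str]] = field(default_factory=list)
    modularity: float = float("nan")

    def members(self, module_id: int) -> set[str]:
        return {n for n, m in self.module_of_node.items() if m == module_id}

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, m in self.module_of_node.items():
            out.setdefault(m, set()).add(n)
        return out


def _components(g: nx.Graph) -> list[set]:
    return sorted((set(c) for c in nx.connected_components(g)), key=min)


def _max_betweenness_edge(g: nx.Graph) -> tuple:
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    best_val = max(eb.values())
    ties = [tuple(sorted(e)) for e, v in eb.items() if v >= best_val - _TIE_TOL]
    return min(ties)


def edge_betweenness_communities(
    g: nx.Graph, target_modules: int | None = None
) -> ModulePartition:
    """Girvan-Newman partition of ``g``.

    With ``target_modules`` the dendrogram is cut at the first partition
    reaching that many modules; otherwise at maximal modularity (the initial
    connected-component partition, modularity >= 0 baseline, is a candidate,
    so graphs with no positive-modularity split stay unsplit).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    work = nx.Graph(g)
    candidates = [_components(work)]
    removals: list[tuple[str, str]] = []
    n_comp = len(candidates[0])
    while work.number_of_edges() > 0:
        edge = _max_betweenness_edge(work)
        work.remove_edge(*edge)
        removals.append(edge)
        comps = _components(work)
        if len(comps) > n_comp:
            n_comp = len(comps)
            candidates.append(comps)
        if target_modules is not None and n_comp >= target_modules:
            break

    if target_modules is not None:
        chosen = candidates[-1]
    else:
        scored = [(nx.community.modularity(g, p) if g.number_of_edges() else 0.0, -len(p), i)
                  for i, p in enumerate(candidates)]
        _, _, idx = max(scored, key=lambda t: (t[0], t[1], -t[2]))
        chosen = candidates[idx]

    module_of_node = {
        node: mid for mid, comp in enumerate(chosen, start=1) for node in comp
    }
    q = nx.community.modularity(g, chosen) if g.number_of_edges() else 0.0
    return ModulePartition(
        module_of_node=module_of_node,
        n_modules=len(chosen),
        removals=removals,
        modularity=q,
    )
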