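"""Functional-interaction (FI) networks: the reference interactome,
condition-specific induced subnetworks, and differential-network subtraction.

A reference interactome is an attributed protein graph: every edge carries a
provenance (curated ``pathway`` interaction vs ``predicted`` by a classifier),
an optional direction, and an effect class (activation, expression
regulation, catalysis, inhibition, unknown). Condition networks are induced
on a gene set (typically the condition's altered genes); subtracting two
condition networks partitions their edges into condition-unique and shared
sets — the differential network.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import networkx as nx

from .aliases import normalize_symbol

PROVENANCES = ("pathway", "predicted", "unknown")
EFFECTS = ("activation", "expression_regulation", "catalysis", "inhibition", "unknown")

EdgeKey = tuple[str, str, str]  # (min symbol, max symbol, provenance)


@dataclass(frozen=True)
class Edge:
    """One functional interaction, oriented u->v when ``directed``."""

    u: str
    v: str
    provenance: str = "unknown"
    directed: bool = False
    effect: str = "unknown"
    raw_u: str | None = None
    raw_v: str | None = None

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError(f"self-loop on {self.u}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def key(self) -> EdgeKey:
        a, b = sorted((self.u, self.v))
        return (a, b, self.provenance)

    @property
    def attrs(self) -> tuple:
        return (self.key, self.directed, self.effect, self.u)


class Interactome:
    """Attributed protein interaction graph.

    Edge identity is the unordered endpoint pair plus provenance; duplicates
    with identical attributes are merged, while attribute conflicts are kept
    as parallel (typically directed) edges under the same key.
    """

    def __init__(self) -> None:
        self._edges: dict[EdgeKey, list[Edge]] = {}

    def add_edge(self, edge: Edge) -> None:
        bucket = self._edges.setdefault(edge.key, [])
        if all(e.attrs != edge.attrs for e in bucket):
            bucket.append(edge)

    def add(self, u: str, v: str, provenance: str = "unknown",
            directed: bool = False, effect: str = "unknown") -> None:
        self.add_edge(Edge(u, v, provenance, directed, effect))

    @property
    def nodes(self) -> list[str]:
        seen: set[str] = set()
        for a, b, _ in self._edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    @property
    def edge_keys(self) -> set[EdgeKey]:
        return set(self._edges)

    def edges(self) -> list[Edge]:
        return [e for key in sorted(self._edges) for e in self._edges[key]]

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def graph(self) -> nx.Graph:
        """Undirected topology (parallel attribute variants collapse)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, prov in self._edges:
            if not g.has_edge(a, b):
                g.add_edge(a, b, provenance=prov)
        return g

    def checksum(self) -> str:
        h = hashlib.sha1()
        for e in self.edges():
            h.update(repr(e.attrs).encode())
        return h.hexdigest()


@dataclass
class ConditionNetwork:
    """Interactome subgraph induced on one condition's gene set."""

    condition: str
    graph: nx.Graph
    member_genes: set[str]
    node_expression: dict[str, float]
    edge_keys: set[EdgeKey]
    ref_checksum: str
    unmapped_genes: list[str] = field(default_factory=list)


@dataclass
class DifferentialNetwork:
    """Edge partition from subtracting condition network B from A."""

    condition_a: str
    condition_b: str
    unique_a: set[EdgeKey]
    unique_b: set[EdgeKey]
    shared: set[EdgeKey]
    nodes_a: set[str] = field(default_factory=set)
    nodes_b: set[str] = field(default_factory=set)

    def node_summary(self) -> dict[str, set[str]]:
        return {
            "unique_a": self.nodes_a - self.nodes_b,
            "unique_b": self.nodes_b - self.nodes_a,
            "shared": self.nodes_a & self.nodes_b,
        }

    @staticmethod
    def _subgraph(keys: set[EdgeKey]) -> nx.Graph:
        g = nx.Graph()
        for a, b, prov in sorted(keys):
            g.add_edge(a, b, provenance=prov)
        return g

    def unique_a_graph(self) -> nx.Graph:
        return self._subgraph(self.unique_a)

    def unique_b_graph(self) -> nx.Graph:
        return self._subgraph(self.unique_b)


def induce_condition_network(
    ref: Interactome,
    genes,
    de=None,
    condition: str = "",
    apply_aliases: bool = True,
) -> ConditionNetwork:
    """Induce the subgraph of ``ref`` on ``genes`` (symbols normalized
    first). ``de`` may be a DE table whose ``log2fc`` column shades nodes.
    Genes absent from the interactome are reported as unmapped."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set: no network can be induced")
    norm = {normalize_symbol(g, apply_aliases) for g in genes}
    ref_nodes = set(ref.nodes)
    mapped = norm & ref_nodes
    unmapped = sorted(norm - ref_nodes)
    if not mapped:
        raise ValueError("no genes map to interactome nodes: no network can be induced")

    keys = {k for k in ref.edge_keys if k[0] in mapped and k[1] in mapped}
    g = nx.Graph()
    g.add_nodes_from(sorted(mapped))
    for a, b, prov in keys:
        if not g.has_edge(a, b):
            g.add_edge(a, b, provenance=prov)

    node_expr: dict[str, float] = {}
    if de is not None:
        lfc = de["log2fc"]
        for gene in mapped:
            if gene in lfc.index:
                node_expr[gene] = float(lfc.loc[gene])
    return ConditionNetwork(
        condition=condition,
        graph=g,
        member_genes=mapped,
        node_expression=node_expr,
        edge_keys=keys,
        ref_checksum=ref.checksum(),
        unmapped_genes=unmapped,
    )


def subtract_networks(a: ConditionNetwork, b: ConditionNetwork) -> DifferentialNetwork:
    """Set-algebra subtraction of two condition networks induced from the
    same reference: edges unique to A, unique to B, and shared.

    Edge identity is the unordered endpoint pair plus provenance; direction
    and effect annotations do not participate in matching.
    """
    if a.ref_checksum != b.ref_checksum:
        raise ValueError(
            "condition networks were induced from different reference interactomes"
        )
    ea, eb = a.edge_keys, b.edge_keys
    return DifferentialNetwork(
        condition_a=a.condition,
        condition_b=b.condition,
        unique_a=ea - eb,
        unique_b=eb - ea,
        shared=ea & eb,
        nodes_a=set(a.graph.nodes),
        nodes_b=set(b.graph.nodes),
    )
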