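"""Drug-target network (DTN) construction and multi-target drug ranking.

A DrugBank-like table of (drug, target) pairs is restricted to the proteins
of a condition- or differential-network: the result is a bipartite graph
linking each drug to its in-network targets. Drugs are then ranked by a
weighted coverage score over the roles their targets play in the network —
bottleneck, hub, or module member — formalizing the intuition that a
multi-target inhibitor hitting several high-centrality proteins is a better
repositioning candidate than a single-target one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .aliases import normalize_symbol

logger = logging.getLogger(__name__)

# Dasatinib: multi-target kinase inhibitor; Src-family kinases plus BCR-ABL,
# EphA2, PDGFR and c-KIT. Raw catalog spellings, normalized on load.
DASATINIB_ID = "DB01254"
DASATINIB_NAME = "Dasatinib"
DASATINIB_TARGETS = ("Fyn", "Yes", "Src", "Lyk", "BCR-ABL", "EphA2", "PDGFR", "c-KIT")

DEFAULT_WEIGHTS = (3.0, 2.0, 1.0)  # bottleneck, hub, plain module member


@dataclass
class DrugTargetTable:
    """(drug_id, drug_name, target) rows; targets normalized, raw kept."""

    frame: pd.DataFrame  # columns: drug_id, drug_name, target_symbol, target_raw

    @classmethod
    def from_records(cls, records, apply_aliases: bool = True) -> "DrugTargetTable":
        """Build from (drug_id, drug_name, raw_target) triples, normalizing
        symbols and dropping duplicate (drug, target) pairs."""
        rows = [
            {
                "drug_id": d,
                "drug_name": name,
                "target_symbol": normalize_symbol(t, apply_aliases),
                "target_raw": t,
            }
            for d, name, t in records
        ]
        df = pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_symbol", "target_raw"])
        df = df.drop_duplicates(subset=["drug_id", "target_symbol"], ignore_index=True)
        return cls(df)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.frame["drug_id"].unique())

    def targets_of(self, drug_id: str) -> set[str]:
        return set(self.frame.loc[self.frame["drug_id"] == drug_id, "target_symbol"])

    def name_of(self, drug_id: str) -> str:
        sub = self.frame.loc[self.frame["drug_id"] == drug_id, "drug_name"]
        return str(sub.iloc[0]) if len(sub) else drug_id


def dasatinib_records() -> list[tuple[str, str, str]]:
    return [(DASATINIB_ID, DASATINIB_NAME, t) for t in DASATINIB_TARGETS]


def build_dtn(table: DrugTargetTable, network_nodes) -> nx.Graph:
    """Bipartite drug-protein graph restricted to ``network_nodes``.

    Drugs with no in-network target are dropped (logged); an entirely empty
    intersection is an error — nothing can be repositioned onto the network.
    """
    if table.frame.empty:
        raise ValueError("empty drug-target table")
    nodes = set(network_nodes)
    g = nx.Graph()
    dropped = 0
    for drug_id in table.drug_ids:
        targets = table.targets_of(drug_id) & nodes
        if not targets:
            dropped += 1
            continue
        g.add_node(drug_id, bipartite="drug", name=table.name_of(drug_id))
        for t in sorted(targets):
            g.add_node(t, bipartite="protein")
            g.add_edge(drug_id, t)
    if dropped:
        logger.info("%d drugs with no in-network target dropped", dropped)
    if g.number_of_edges() == 0:
        raise ValueError("no drug targets any network protein: no repositionable drug")
    return g


def score_drugs(
    dtn: nx.Graph,
    centrality: pd.DataFrame,
    modules=None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Rank drugs by weighted coverage of bottlenecks, hubs and module
    members.

    Each covered target counts once, in its highest-weight eligible role;
    score = w_b * n_bottlenecks + w_h * n_hubs + w_m * n_members. Ties break
    toward more covered targets, then drug id.
    """
    w_b, w_h, w_m = (float(w) for w in weights)
    if min(w_b, w_h, w_m) < 0 or (w_b == w_h == w_m == 0):
        raise ValueError("weights must be nonnegative and not all zero")
    bottlenecks = set(centrality.index[centrality["is_bottleneck"]])
    hubs = set(centrality.index[centrality["is_hub"]])
    members = set(modules.module_of_node) if modules is not None else set(centrality.index)

    drug_nodes = sorted(
        n for n, d in dtn.nodes(data=True) if d.get("bipartite") == "drug"
    )
    rows = []
    for drug in drug_nodes:
        covered = sorted(dtn.neighbors(drug))
        nb = nh = nm = 0
        for t in covered:
            roles = []
            if t in bottlenecks:
                roles.append((w_b, "b"))
            if t in hubs:
                roles.append((w_h, "h"))
            if t in members:
                roles.append((w_m, "m"))
            if not roles:
                continue
            role = max(roles)[1]
            nb += role == "b"
            nh += role == "h"
            nm += role == "m"
        rows.append(
            {
                "drug_id": drug,
                "drug_name": dtn.nodes[drug].get("name", drug),
                "n_bottlenecks_hit": nb,
                "n_hubs_hit": nh,
                "n_module_hit": nm,
                "n_covered": len(covered),
                "covered_targets": ",".join(covered),
                "score": w_b * nb + w_h * nh + w_m * nm,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["score", "n_covered", "drug_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df.set_index("drug_id")
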