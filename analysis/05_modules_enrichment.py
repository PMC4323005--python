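#!/usr/bin/env python
"""Edge-betweenness modules, pathway enrichment and preranked GSEA.

Partitions the up-signature network with Girvan-Newman clustering, tests
each module for pathway over-representation (hypergeometric, BH), builds
the enrichment map, and runs preranked GSEA on the full log2FC ranking.
"""

import argparse
from pathlib import Path

import networkx as nx
import pandas as pd

from diffnet.communities import edge_betweenness_communities
from diffnet.enrichment import build_enrichment_map, enrich_modules, gsea_preranked
from diffnet.io import read_gmt

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    inputs = args.study / "inputs"

    edges = pd.concat([
        pd.read_csv(args.study / "diffnet_unique_up.tsv", sep="\t"),
        pd.read_csv(args.study / "diffnet_shared.tsv", sep="\t"),
    ])
    g = nx.from_pandas_edgelist(edges, "source", "target")
    part = edge_betweenness_communities(g)
    pd.Series(part.module_of_node, name="module").rename_axis("node").sort_index(
    ).to_csv(args.study / "modules.tsv", sep="\t")
    print(f"{part.n_modules} modules at modularity {part.modularity:.3f} "
          f"(sizes {sorted(map(len, part.modules().values()), reverse=True)})")

    sets = read_gmt(inputs / "gene_sets.gmt")
    universe = set(pd.read_csv(inputs / "expression.tsv", sep="\t", index_col=0).index)
    rows = enrich_modules(part, sets, universe=universe)
    rows.to_csv(args.study / "enrichment.tsv", sep="\t", index=False)
    sig = rows[rows["fdr"] < 0.001]
    print(f"{len(sig)}/{len(rows)} module-set tests significant at FDR < 0.001:")
    print(sig[["module", "set", "k", "K", "p", "fdr"]].to_string(index=False))

    emap = build_enrichment_map(rows, sets, fdr_cutoff=0.001)
    nx.write_graphml(emap, args.study / "enrichment_map.graphml")

    de = pd.read_csv(args.study / "de_table.tsv", sep="\t", index_col=0)
    ranked = de["log2fc"].sort_values(ascending=False)
    gsea = gsea_preranked(ranked, sets, n_perm=1000, seed=args.seed)
    gsea.to_csv(args.study / "gsea.tsv", sep="\t", index=False)
    top = gsea.sort_values("nes", ascending=False).head(4)
    print("top GSEA sets by NES (community sets should lead):")
    print(top[["set", "es", "nes", "p_perm", "fdr"]].to_string(index=False))


if __name__ == "__main__":
    main()
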