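#!/usr/bin/env python
"""Condition networks and the differential network.

Induces the up- and down-regulated signature subnetworks from the reference
interactome and subtracts them into condition-unique and shared edge sets.
"""

import argparse
from pathlib import Path

import pandas as pd

from diffnet.io import read_interactome
from diffnet.network import induce_condition_network, subtract_networks

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()
    inputs = args.study / "inputs"

    ref_net = read_interactome(inputs / "interactome.tsv")
    de = pd.read_csv(args.study / "de_table.tsv", sep="\t", index_col=0)
    signature = set((args.study / "signature.txt").read_text().split())
    up = {g for g in signature if de.loc[g, "log2fc"] > 0}
    down = signature - up

    net_up = induce_condition_network(ref_net, up, de, "tumor_up")
    net_down = induce_condition_network(ref_net, down, de, "tumor_down")
    dn = subtract_networks(net_up, net_down)

    for name, keys in (("unique_up", dn.unique_a), ("unique_down", dn.unique_b),
                       ("shared", dn.shared)):
        pd.DataFrame(sorted(keys), columns=["source", "target", "provenance"]).to_csv(
            args.study / f"diffnet_{name}.tsv", sep="\t", index=False)

    print(f"up-signature network: {net_up.graph.number_of_nodes()} nodes, "
          f"{len(net_up.edge_keys)} edges "
          f"({len(net_up.unmapped_genes)} signature genes not in interactome)")
    print(f"down-signature network: {net_down.graph.number_of_nodes()} nodes, "
          f"{len(net_down.edge_keys)} edges")
    print(f"differential network: {len(dn.unique_a)} edges unique to the "
          f"up network, {len(dn.unique_b)} unique to down, {len(dn.shared)} shared")


if __name__ == "__main__":
    main()
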