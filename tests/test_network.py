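"""Interactome parsing, condition-network induction and subtraction algebra."""

import numpy as np
import pytest

from diffnet.io import read_interactome, write_edge_tsv
from diffnet.network import (
    Interactome,
    induce_condition_network,
    subtract_networks,
)
from diffnet.synth import SyntheticSpec, gen_interactome


def random_interactome(seed: int, n_nodes: int = 30, n_edges: int = 60) -> Interactome:
    rng = np.random.default_rng(seed)
    inter = Interactome()
    nodes = [f"P{i:02d}" for i in range(n_nodes)]
    while inter.n_edges < n_edges:
        u, v = rng.choice(nodes, size=2, replace=False)
        inter.add(str(u), str(v),
                  provenance=str(rng.choice(["pathway", "predicted"])),
                  directed=bool(rng.random() < 0.5),
                  effect=str(rng.choice(["activation", "inhibition", "unknown"])))
    return inter


class TestReaders:
    def test_sif_single_line(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\tFI\tB\n")
        inter = read_interactome(p)
        assert inter.nodes == ["A", "B"]
        (edge,) = inter.edges()
        assert edge.provenance == "unknown" and not edge.directed

    def test_edge_tsv_round_trip_preserves_inhibition(self, tmp_path):
        inter = Interactome()
        inter.add("TAZ1", "PDGFRB", provenance="pathway", directed=True,
                  effect="inhibition")
        p = tmp_path / "net.tsv"
        write_edge_tsv(inter, p)
        back = read_interactome(p)
        (edge,) = back.edges()
        assert edge.effect == "inhibition" and edge.directed
        assert edge.key == ("PDGFRB", "TAZ1", "pathway")

    def test_malformed_sif_reports_line_number(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\tFI\tB\nbroken line\n")
        with pytest.raises(ValueError, match="line 2"):
            read_interactome(p)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_interactome(tmp_path / "net.xyz")

    def test_random_file_counts_match_line_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        lines, pairs = [], set()
        for _ in range(100):
            u, v = rng.choice(50, size=2, replace=False)
            lines.append(f"N{u:02d}\tFI\tN{v:02d}")
            pairs.add(frozenset((f"N{u:02d}", f"N{v:02d}")))
        p = tmp_path / "rand.sif"
        p.write_text("\n".join(lines) + "\n")
        inter = read_interactome(p)
        assert inter.n_edges == len(pairs)
        assert set(inter.nodes) == {n for pair in pairs for n in pair}

    def test_symbols_alias_mapped(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("Lyk\tFI\tc-KIT\nYes\tFI\tBCR-ABL\n")
        inter = read_interactome(p)
        assert set(inter.nodes) == {"LCK", "KIT", "YES1", "ABL1"}

    def test_duplicate_edges_merge_conflicts_parallel(self):
        inter = Interactome()
        inter.add("A", "B", "pathway", True, "activation")
        inter.add("B", "A", "pathway", True, "activation")  # same oriented edge? no: B->A
        inter.add("A", "B", "pathway", True, "activation")  # exact duplicate
        assert len(inter._edges[("A", "B", "pathway")]) == 2
        assert inter.n_edges == 1


class TestInduction:
    def test_full_gene_set_reproduces_reference(self):
        inter, _ = gen_interactome(SyntheticSpec(seed=2))
        net = induce_condition_network(inter, inter.nodes, condition="all")
        assert net.edge_keys == inter.edge_keys
        assert set(net.graph.nodes) == set(inter.nodes)

    def test_two_gene_induction(self):
        inter = Interactome()
        inter.add("A", "B")
        inter.add("B", "C")
        net = induce_condition_network(inter, ["A", "B"])
        assert net.edge_keys == {("A", "B", "unknown")}

    def test_random_subset_matches_brute_force_filter(self):
        inter = random_interactome(1)
        rng = np.random.default_rng(5)
        genes = set(rng.choice(inter.nodes, size=15, replace=False))
        net = induce_condition_network(inter, genes)
        oracle = {e.key for e in inter.edges() if e.key[0] in genes and e.key[1] in genes}
        assert net.edge_keys == oracle

    def test_unmapped_genes_reported(self):
        inter = Interactome()
        inter.add("A", "B")
        net = induce_condition_network(inter, ["A", "B", "NOTTHERE"])
        assert net.unmapped_genes == ["NOTTHERE"]

    def test_no_mapped_genes_is_error(self):
        inter = Interactome()
        inter.add("A", "B")
        with pytest.raises(ValueError, match="no network can be induced"):
            induce_condition_network(inter, ["X", "Y"])
        with pytest.raises(ValueError, match="no network can be induced"):
            induce_condition_network(inter, [])

    def test_induction_monotone_in_gene_set(self):
        inter = random_interactome(3)
        small = set(inter.nodes[:10])
        large = small | set(inter.nodes[10:20])
        net_s = induce_condition_network(inter, small)
        net_l = induce_condition_network(inter, large)
        assert net_s.edge_keys <= net_l.edge_keys


class TestSubtraction:
    @staticmethod
    def nets(seed, size_a=18, size_b=18):
        inter = random_interactome(seed)
        rng = np.random.default_rng(seed + 100)
        ga = rng.choice(inter.nodes, size=size_a, replace=False)
        gb = rng.choice(inter.nodes, size=size_b, replace=False)
        a = induce_condition_network(inter, ga, condition="a")
        b = induce_condition_network(inter, gb, condition="b")
        return a, b

    def test_self_subtraction_all_shared(self):
        a, _ = self.nets(0)
        dn = subtract_networks(a, a)
        assert dn.unique_a == set() and dn.unique_b == set()
        assert dn.shared == a.edge_keys

    def test_explicit_three_edge_example(self):
        inter = Interactome()
        for u, v in [("A", "B"), ("B", "C"), ("C", "D")]:
            inter.add(u, v)
        a = induce_condition_network(inter, ["A", "B", "C", "D"], condition="a")
        b = induce_condition_network(inter, ["B", "C"], condition="b")
        dn = subtract_networks(a, b)
        assert dn.unique_a == {("A", "B", "unknown"), ("C", "D", "unknown")}
        assert dn.shared == {("B", "C", "unknown")}
        assert dn.unique_b == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_matches_set_algebra_oracle(self, seed):
        a, b = self.nets(seed)
        dn = subtract_networks(a, b)
        ea, eb = set(a.edge_keys), set(b.edge_keys)
        assert dn.unique_a == ea - eb
        assert dn.unique_b == eb - ea
        assert dn.shared == ea & eb
        # disjointness + reconstruction + edge-count identity
        assert not (dn.unique_a & dn.shared) and not (dn.unique_b & dn.shared)
        assert dn.unique_a | dn.shared == ea
        assert dn.unique_b | dn.shared == eb
        assert len(dn.unique_a) + len(dn.unique_b) + 2 * len(dn.shared) == len(ea) + len(eb)

    def test_swap_symmetry(self):
        a, b = self.nets(4)
        fwd, rev = subtract_networks(a, b), subtract_networks(b, a)
        assert fwd.unique_a == rev.unique_b
        assert fwd.unique_b == rev.unique_a
        assert fwd.shared == rev.shared

    def test_different_references_rejected(self):
        a, _ = self.nets(0)
        b, _ = self.nets(1)
        with pytest.raises(ValueError, match="different reference"):
            subtract_networks(a, b)

    def test_node_summary_partition(self):
        a, b = self.nets(6)
        summary = subtract_networks(a, b).node_summary()
        na, nb = set(a.graph.nodes), set(b.graph.nodes)
        assert summary["unique_a"] == na - nb
        assert summary["shared"] == na & nb
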