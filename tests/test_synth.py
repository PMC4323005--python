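"""Generator properties: determinism, planted structure, fixture fidelity."""

import networkx as nx
import numpy as np
import pytest

from diffnet.drugs import DASATINIB_TARGETS
from diffnet.synth import (
    SyntheticSpec,
    gen_drug_table,
    gen_expression,
    gen_genesets,
    gen_interactome,
    gen_lda_data,
)


class TestGenExpression:
    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(seed=5)
        m1, _ = gen_expression(spec)
        m2, _ = gen_expression(spec)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        assert m1.sample_ids == m2.sample_ids

    def test_null_model_plants_nothing(self):
        spec = SyntheticSpec(n_de_genes=0, planted_log2fc=0.0, seed=1, n_bridges=0,
                             n_communities=1)
        m, truth = gen_expression(spec)
        assert truth.de_gene_ids == set()
        assert m.counts.shape == (spec.n_genes, 12)

    def test_condition_shift_matches_planted_sign(self):
        m, truth = gen_expression(SyntheticSpec(seed=2))
        up = sorted(truth.up_gene_ids)
        down = sorted(truth.de_gene_ids - truth.up_gene_ids)
        df = m.to_frame()
        case = [s for s in m.sample_ids if m.condition_of_sample[s] == "cond2"]
        ctrl = [s for s in m.sample_ids if m.condition_of_sample[s] == "cond1"]
        up_fc = (df.loc[up, case].mean(axis=1) + 1) / (df.loc[up, ctrl].mean(axis=1) + 1)
        down_fc = (df.loc[down, case].mean(axis=1) + 1) / (df.loc[down, ctrl].mean(axis=1) + 1)
        assert (up_fc > 1).mean() > 0.95
        assert (down_fc < 1).mean() > 0.95

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_de_genes=700), dict(samples_per_condition=1), dict(dispersion=0.0)],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            gen_expression(SyntheticSpec(**kwargs))


class TestGenInteractome:
    def test_deterministic_edge_list(self):
        spec = SyntheticSpec(seed=9)
        i1, _ = gen_interactome(spec)
        i2, _ = gen_interactome(spec)
        assert [e.attrs for e in i1.edges()] == [e.attrs for e in i2.edges()]

    def test_single_bridge_has_largest_betweenness(self):
        spec = SyntheticSpec(n_communities=2, n_bridges=1, seed=3)
        inter, truth = gen_interactome(spec)
        (bridge,) = truth.bridge_nodes
        case = inter.graph().subgraph(truth.community_of_node)
        bw = nx.betweenness_centrality(case, normalized=False)
        others = [v for n, v in bw.items() if n != bridge]
        assert bw[bridge] > max(others)

    def test_no_bridges_single_connected_module(self):
        spec = SyntheticSpec(n_communities=1, n_bridges=0, seed=4)
        inter, truth = gen_interactome(spec)
        case = inter.graph().subgraph(truth.community_of_node)
        assert nx.is_connected(case)
        assert truth.bridge_nodes == set()

    def test_bridges_are_articulation_points(self, scenario_graph):
        inter, truth = scenario_graph
        case = inter.graph().subgraph(truth.community_of_node)
        arts = set(nx.articulation_points(case))
        assert truth.bridge_nodes <= arts

    def test_too_many_bridges_rejected(self):
        with pytest.raises(ValueError):
            gen_interactome(SyntheticSpec(n_communities=2, n_bridges=2))

    def test_every_bridge_in_community_map(self, scenario_graph):
        _, truth = scenario_graph
        assert truth.bridge_nodes <= set(truth.community_of_node)


class TestGenGenesets:
    def test_community_sets_exact(self, scenario_graph):
        _, truth = scenario_graph
        coll = gen_genesets(truth, SyntheticSpec(seed=11))
        for c in sorted(set(truth.community_of_node.values())):
            members = {n for n, cc in truth.community_of_node.items() if cc == c}
            assert coll.sets[f"community_{c}"] == members

    def test_decoy_overlap_matches_hypergeometric_mean(self, scenario_graph):
        # E[overlap] of a uniform size-n draw with a fixed size-K set is n*K/N
        _, truth = scenario_graph
        spec = SyntheticSpec(seed=11)
        community_1 = {n for n, c in truth.community_of_node.items() if c == 1}
        overlaps, sizes = [], []
        for s in range(40):
            coll = gen_genesets(truth, spec, n_decoys=3, seed=s)
            for i in range(1, 4):
                decoy = coll.sets[f"decoy_{i}"]
                overlaps.append(len(decoy & community_1))
                sizes.append(len(decoy))
        N = spec.n_genes
        expected = np.mean([n * len(community_1) / N for n in sizes])
        assert abs(np.mean(overlaps) - expected) < 3 * np.std(overlaps) / np.sqrt(len(overlaps)) + 0.05


class TestGenDrugTable:
    def test_dasatinib_fixture_has_eight_verbatim_targets(self, scenario_graph):
        _, truth = scenario_graph
        table, _ = gen_drug_table(truth, SyntheticSpec(seed=11))
        raw = set(table.frame.loc[table.frame["drug_name"] == "Dasatinib", "target_raw"])
        assert raw == set(DASATINIB_TARGETS)
        assert len(DASATINIB_TARGETS) == 8

    def test_minimal_table_is_planted_plus_dasatinib(self, scenario_graph):
        _, truth = scenario_graph
        table, truth2 = gen_drug_table(truth, SyntheticSpec(n_drugs=1, seed=11))
        assert set(table.drug_ids) == {truth2.planted_drug_id, "DB01254"}

    def test_planted_targets_cover_bridges(self, scenario_graph):
        _, truth = scenario_graph
        spec = SyntheticSpec(planted_drug_targets=len(truth.bridge_nodes), seed=11)
        table, truth2 = gen_drug_table(truth, spec)
        assert truth.bridge_nodes <= table.targets_of(truth2.planted_drug_id)

    def test_too_many_planted_targets_rejected(self, scenario_graph):
        _, truth = scenario_graph
        n_eligible = len(truth.bridge_nodes | set(truth.hub_nodes))
        with pytest.raises(ValueError):
            gen_drug_table(truth, SyntheticSpec(planted_drug_targets=n_eligible + 1))


class TestGenLdaData:
    def test_deterministic(self):
        a = gen_lda_data(1e-4, seed=3)
        b = gen_lda_data(1e-4, seed=3)
        assert a.frame.equals(b.frame)

    def test_tiny_frequency_all_negative(self):
        exp = gen_lda_data(1e-12, doses=[1000], replicates_per_dose=20, seed=0)
        assert exp.positive.sum() == 0

    def test_saturating_dose_all_positive(self):
        # dose 1e6 at f=1e-3: P(negative) = exp(-1000) ~ 0
        exp = gen_lda_data(1e-3, doses=[10**6], replicates_per_dose=20, seed=0)
        assert (exp.positive == exp.injected).all()

    def test_rejects_bad_frequency(self):
        for f in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                gen_lda_data(f)
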