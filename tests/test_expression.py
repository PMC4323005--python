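"""Normalization, differential testing and signature-filter semantics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffnet.expression import (
    ExpressionMatrix,
    de_test,
    filter_signature,
    normalize_counts,
    size_factors_median_ratio,
)
from diffnet.synth import SyntheticSpec, gen_expression


def matrix_from(counts, conditions=None):
    counts = np.asarray(counts, dtype=float)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    cond = conditions or {s: "a" for s in samples}
    return ExpressionMatrix(genes, samples, counts, cond)


def two_group_matrix(a_block, b_block):
    a_block, b_block = np.asarray(a_block, float), np.asarray(b_block, float)
    counts = np.hstack([a_block, b_block])
    samples = [f"s{j}" for j in range(counts.shape[1])]
    cond = {s: ("a" if j < a_block.shape[1] else "b") for j, s in enumerate(samples)}
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return ExpressionMatrix(genes, samples, counts, cond)


class TestNormalization:
    def test_cpm_column_sum(self):
        m = normalize_counts(matrix_from([[1], [2], [3]]), "cpm")
        assert m.counts.sum() == pytest.approx(1e6)

    def test_median_ratio_identical_samples_unit_factors(self):
        counts = np.tile([[3.0], [7.0], [11.0]], (1, 2))
        sf = size_factors_median_ratio(matrix_from(counts))
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_median_ratio_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 0.3, size=(20, 6)).astype(float) + 1
        m = matrix_from(counts)
        sf = size_factors_median_ratio(m)
        # oracle: literal median-of-ratios definition, gene by gene
        ref = np.array([math.exp(np.mean(np.log(row))) for row in counts])
        oracle = [np.median([counts[g, j] / ref[g] for g in range(20)]) for j in range(6)]
        np.testing.assert_allclose(sf, oracle, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(matrix_from([[1, 0], [2, 0]]), "cpm")

    def test_no_all_positive_gene_names_condition(self):
        with pytest.raises(ValueError, match="positive counts in every sample"):
            normalize_counts(matrix_from([[1, 0], [0, 2]]), "median_ratio")


def brute_force_permutation_p(a_vals, b_vals, pseudocount=0.5):
    """Exhaustive two-sided permutation p for the mean log2 difference."""
    pooled = np.log2(np.concatenate([a_vals, b_vals]) + pseudocount)
    na, nb = len(a_vals), len(b_vals)
    obs = pooled[na:].mean() - pooled[:na].mean()
    count = total = 0
    for b_idx in itertools.combinations(range(na + nb), nb):
        mask = np.zeros(na + nb, dtype=bool)
        mask[list(b_idx)] = True
        stat = pooled[mask].mean() - pooled[~mask].mean()
        count += abs(stat) >= abs(obs) - 1e-12
        total += 1
    return count / total


class TestDeTest:
    def test_identical_groups_null_result(self):
        m = two_group_matrix([[5, 5, 5]], [[5, 5, 5]])
        res = de_test(m, "a", "b", test="permutation")
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_permutation_matches_exhaustive_enumeration_3v3(self):
        rng = np.random.default_rng(42)
        A = rng.poisson(40, size=(8, 3)).astype(float)
        B = rng.poisson(70, size=(8, 3)).astype(float)
        res = de_test(two_group_matrix(A, B), "a", "b", test="permutation")
        for i in range(8):
            expected = brute_force_permutation_p(A[i], B[i])
            assert res["p_value"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_planted_log2fc_estimated_accurately(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = SyntheticSpec(seed=seed, dispersion=0.05, n_subtypes=1)
            m, truth = gen_expression(spec)
            res = de_test(normalize_counts(m), "cond1", "cond2")
            est = res.loc[sorted(truth.up_gene_ids), "log2fc"]
            hits += (est.sub(2.0).abs() < 0.5).mean() >= 0.9
        assert hits >= 0.9 * n_seeds

    def test_swapping_conditions_negates_log2fc(self):
        m, _ = gen_expression(SyntheticSpec(seed=8))
        norm = normalize_counts(m)
        fwd = de_test(norm, "cond1", "cond2")
        rev = de_test(norm, "cond2", "cond1")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_null_permutation_p_super_uniform(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(1000, 6)).astype(float)
        res = de_test(matrix_from(counts, {f"s{j}": ("a" if j < 3 else "b")
                                           for j in range(6)}), "a", "b",
                      test="permutation")
        for alpha in (0.05, 0.1, 0.25):
            assert (res["p_value"] <= alpha).mean() <= alpha + 0.03

    def test_adjusted_p_dominates_raw(self):
        m, _ = gen_expression(SyntheticSpec(seed=8))
        res = de_test(normalize_counts(m), "cond1", "cond2")
        assert (res["adj_p"] >= res["p_value"] - 1e-15).all()

    def test_errors(self):
        m = two_group_matrix([[1, 2]], [[3, 4]])
        with pytest.raises(ValueError, match="unknown condition"):
            de_test(m, "a", "zzz")
        single = matrix_from([[1, 2]], {"s0": "a", "s1": "b"})
        with pytest.raises(ValueError, match="at least 2 samples"):
            de_test(single, "a", "b")


class TestFilterSignature:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            [{"log2fc": fc, "p_value": p} for _, fc, p in rows],
            index=[g for g, _, _ in rows],
        )

    def test_threshold_semantics_strict_fold(self):
        # 1.2 log2 units ~ 2.30-fold passes; exactly 2.0-fold is excluded
        t = self.table([("keep", 1.2, 0.01), ("boundary", 1.0, 0.01),
                        ("weak_p", 1.2, 0.05), ("down", -1.3, 0.001)])
        assert filter_signature(t) == ["down", "keep"]

    def test_multi_profile_conjunction(self):
        t1 = self.table([("g1", 2.0, 0.01), ("g2", 2.0, 0.01)])
        t2 = self.table([("g1", 2.0, 0.01), ("g2", 0.1, 0.9)])
        assert filter_signature([t1, t2]) == ["g1"]

    def test_empty_results_empty_set(self):
        assert filter_signature([]) == []

    @given(fc=st.floats(2.0, 8.0), p=st.floats(0.001, 0.05))
    @settings(max_examples=25, deadline=None)
    def test_tightening_thresholds_never_adds_genes(self, fc, p):
        t = self.table([(f"g{i}", lfc, pv) for i, (lfc, pv) in enumerate(
            [(0.5, 0.2), (1.5, 0.01), (2.5, 0.2), (3.0, 0.001), (-2.0, 0.04)])])
        base = set(filter_signature(t))
        assert set(filter_signature(t, fc_threshold=fc, p_threshold=p)) <= base
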