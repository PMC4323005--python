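"""Expression matrices, normalization, differential-expression testing and
the fold-change / p-value signature filter.

The pipeline starts from a gene x sample count matrix with a condition label
per sample. Counts are library-size normalized (CPM or DESeq-style median of
ratios), tested per gene between two conditions (Welch t on log2 counts, or
a label-permutation test of the mean log difference), and genes are retained
in the signature when they exceed a fold-change threshold at a raw p-value
cutoff — by default stricter than 2.0-fold with p < 0.05, jointly in every
configured contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with a condition label per sample."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        missing = [s for s in self.sample_ids if s not in self.condition_of_sample]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and nonnegative")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of_sample[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of_sample[s] == condition]

    def column_indices(self, samples: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in samples], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        idx = [self.gene_ids.index(g) for g in keep]
        return ExpressionMatrix(
            keep, list(self.sample_ids), self.counts[idx, :], dict(self.condition_of_sample)
        )


def size_factors_median_ratio(m: ExpressionMatrix) -> np.ndarray:
    """DESeq-style size factors: per-sample median of ratios to the
    geometric-mean reference profile, over genes positive in all samples."""
    counts = m.counts
    all_pos = np.all(counts > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "median_ratio normalization requires at least one gene with "
            "positive counts in every sample; none found"
        )
    sub = counts[all_pos, :]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / ref[:, None], axis=0)


def normalize_counts(m: ExpressionMatrix, method: str = "median_ratio") -> ExpressionMatrix:
    """Library-size normalize columns.

    ``cpm`` rescales each sample to a total of 1e6; ``median_ratio`` divides
    each sample by its median-of-ratios size factor.
    """
    totals = m.counts.sum(axis=0)
    zero = [s for s, t in zip(m.sample_ids, totals) if t <= 0]
    if zero:
        raise ValueError(f"samples with zero total count cannot be normalized: {zero}")
    if method == "cpm":
        scaled = m.counts * (1e6 / totals)[None, :]
    elif method == "median_ratio":
        sf = size_factors_median_ratio(m)
        scaled = m.counts / sf[None, :]
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), scaled, dict(m.condition_of_sample)
    )


def _permutation_pvalues(
    log_a: np.ndarray,
    log_b: np.ndarray,
    n_perm: int,
    seed: int,
    max_exact: int = 2000,
) -> np.ndarray:
    """Two-sided label-permutation p-values for the mean log difference.

    Enumerates all label splits when feasible (then p is exact, the observed
    split included in the numerator by construction); otherwise Monte-Carlo
    with add-one smoothing.
    """
    na, nb = log_a.shape[1], log_b.shape[1]
    pooled = np.hstack([log_a, log_b])
    n = na + nb
    obs = log_b.mean(axis=1) - log_a.mean(axis=1)
    from math import comb

    n_splits = comb(n, nb)
    tol = 1e-12
    if n_splits <= max_exact:
        count = np.zeros(pooled.shape[0], dtype=int)
        for b_idx in itertools.combinations(range(n), nb):
            mask = np.zeros(n, dtype=bool)
            mask[list(b_idx)] = True
            stat = pooled[:, mask].mean(axis=1) - pooled[:, ~mask].mean(axis=1)
            count += np.abs(stat) >= np.abs(obs) - tol
        return count / n_splits
    rng = np.random.default_rng(seed)
    count = np.zeros(pooled.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:nb]] = True
        stat = pooled[:, mask].mean(axis=1) - pooled[:, ~mask].mean(axis=1)
        count += np.abs(stat) >= np.abs(obs) - tol
    return (1 + count) / (1 + n_perm)


def de_test(
    m: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    test: str = "welch_log",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene differential test of ``cond_b`` versus ``cond_a``.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (log2 of the
    pseudocounted condition-mean ratio, b over a), ``p_value``, ``adj_p``
    (Benjamini-Hochberg across genes) and ``passes_filter``.
    """
    for cond in (cond_a, cond_b):
        if cond not in m.conditions:
            raise ValueError(f"unknown condition label: {cond!r}")
    a_cols = m.column_indices(m.samples_of(cond_a))
    b_cols = m.column_indices(m.samples_of(cond_b))
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each condition needs at least 2 samples")

    c = pseudocount
    A, B = m.counts[:, a_cols], m.counts[:, b_cols]
    log2fc = np.log2((B.mean(axis=1) + c) / (A.mean(axis=1) + c))
    log_a, log_b = np.log2(A + c), np.log2(B + c)

    if test == "welch_log":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
        # zero variance in both groups: separation decides, not the t statistic
        nan = ~np.isfinite(p)
        p = np.where(nan, np.where(np.abs(log2fc) > 1e-12, 0.0, 1.0), p)
    elif test == "permutation":
        p = _permutation_pvalues(log_a, log_b, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown test: {test!r}")

    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    passes = (np.abs(log2fc) > np.log2(fc_threshold)) & (p < p_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
            "passes_filter": passes,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )


def filter_signature(
    results,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[str]:
    """Genes with |fold change| strictly above ``fc_threshold`` and raw
    p below ``p_threshold``, in *every* supplied contrast.

    ``results`` is one DE table or a list of them (conjunction semantics:
    with several expression profiles a signature gene must pass in all).
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if isinstance(results, pd.DataFrame):
        results = [results]
    results = list(results)
    if not results:
        return []
    kept: set[str] | None = None
    for res in results:
        ok = (np.abs(res["log2fc"]) > np.log2(fc_threshold)) & (
            res["p_value"] < p_threshold
        )
        genes = set(res.index[ok])
        kept = genes if kept is None else kept & genes
    return sorted(kept or set())
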