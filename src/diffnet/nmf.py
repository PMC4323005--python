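"""Consensus nonnegative matrix factorization for subtype discovery.

Repeated NMF runs from random nonnegative initializations assign each sample
to the metagene (row of H) on which it loads most strongly. The fraction of
runs in which two samples co-cluster forms the consensus matrix; average-
linkage hierarchical clustering of 1 - consensus yields the final labels,
and the cophenetic correlation of that dendrogram scores cluster stability.
K is chosen to maximize the cophenetic correlation (ties toward smaller K),
automating the usual visual inspection of per-K consensus heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

_EPS = 1e-10


def nmf_factorize(
    abundance: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    return_objective: bool = False,
):
    """Frobenius NMF by multiplicative updates from a random nonnegative init.

    Returns (W, H) with W genes x k and H k x samples. The Frobenius
    objective is non-increasing per update; iteration stops when its relative
    change drops below ``tol`` or at ``max_iter``.
    """
    V = np.asarray(abundance, dtype=float)
    if V.ndim != 2:
        raise ValueError("abundance must be a 2-D matrix")
    if np.any(V < 0):
        raise ValueError("abundance matrix must be nonnegative")
    if not 1 <= k < min(V.shape):
        raise ValueError(f"k={k} must satisfy 1 <= k < min{V.shape}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(V.shape[0], k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, V.shape[1])) * scale

    objective = [float(np.linalg.norm(V - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        objective.append(obj)
        prev = objective[-2]
        if prev - obj <= tol * max(prev, _EPS):
            break
    if return_objective:
        return W, H, objective
    return W, H


def cluster_labels(H: np.ndarray) -> np.ndarray:
    """Hard sample assignments: argmax metagene per column, 1-based."""
    return np.argmax(H, axis=0) + 1


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray
    labels: dict[str, int]
    cophenetic: float
    n_runs: int
    sample_ids: list[str] = field(default_factory=list)

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.consensus, index=self.sample_ids, columns=self.sample_ids)


def _cophenetic_correlation(linkage_matrix: np.ndarray, condensed: np.ndarray) -> float:
    coph_dists = cophenet(linkage_matrix)
    if np.std(condensed) == 0 or np.std(coph_dists) == 0:
        # degenerate (e.g. perfectly block 0/1 consensus collapsing to equal
        # distances): the dendrogram reproduces the distances exactly
        return 1.0 if np.allclose(condensed, coph_dists) else 0.0
    return float(np.corrcoef(condensed, coph_dists)[0, 1])


def consensus_cluster(
    abundance: np.ndarray,
    k: int,
    n_runs: int = 1000,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ConsensusResult:
    """Average-connectivity consensus matrix over ``n_runs`` NMF runs at a
    fixed K, with final labels from average-linkage clustering of
    1 - consensus and the cophenetic correlation of that dendrogram."""
    V = np.asarray(abundance, dtype=float)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    n_samples = V.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]

    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    consensus = np.zeros((n_samples, n_samples))
    for rs in run_seeds:
        _, H = nmf_factorize(V, k, seed=int(rs), tol=tol, max_iter=max_iter)
        lab = cluster_labels(H)
        consensus += lab[:, None] == lab[None, :]
    consensus /= n_runs
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)

    condensed = squareform(1.0 - consensus, checks=False)
    Z = average(condensed)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusResult(
        k=k,
        consensus=consensus,
        labels={s: int(l) for s, l in zip(sample_ids, labels)},
        cophenetic=_cophenetic_correlation(Z, condensed),
        n_runs=n_runs,
        sample_ids=list(sample_ids),
    )


@dataclass
class KSelection:
    best_k: int
    table: pd.DataFrame  # per-k cophenetic correlations
    results: dict[int, ConsensusResult]


def select_k(
    abundance: np.ndarray,
    k_range,
    n_runs: int = 100,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    **kwargs,
) -> KSelection:
    """Pick K maximizing the cophenetic correlation over ``k_range``
    (ties broken toward smaller K); all per-K results are retained."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    results: dict[int, ConsensusResult] = {}
    for i, k in enumerate(ks):
        results[k] = consensus_cluster(
            abundance, k, n_runs=n_runs, seed=seed + 1000 * i,
            sample_ids=sample_ids, **kwargs,
        )
    table = pd.DataFrame(
        {"k": ks, "cophenetic": [results[k].cophenetic for k in ks]}
    ).set_index("k")
    best_k = min(ks, key=lambda k: (-results[k].cophenetic, k))
    return KSelection(best_k=best_k, table=table, results=results)


def scale_rows_unit_max(abundance: np.ndarray) -> np.ndarray:
    """Scale each gene (row) to unit maximum so no single high-abundance
    gene dominates the factorization; all-zero rows stay zero."""
    V = np.asarray(abundance, dtype=float)
    mx = V.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return V / mx
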