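"""Gene-set enrichment: hypergeometric over-representation with
Benjamini-Hochberg control, enrichment-map construction, and preranked GSEA.

Over-representation of a module's genes in a pathway set uses the
hypergeometric upper tail P(X >= k) against a stated universe (the "gene
study set"). Significant sets are assembled into an enrichment map — a graph
whose nodes are gene sets (size attribute = member count) linked by
hierarchy (parent -> child) or by membership overlap. Preranked GSEA is the
classic weighted Kolmogorov-Smirnov running sum with a gene-label
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional universe and set hierarchy."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None
    parent_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.parent_of:
            # hierarchy must be acyclic
            for start in self.parent_of:
                seen = {start}
                node = start
                while node in self.parent_of:
                    node = self.parent_of[node]
                    if node in seen:
                        raise ValueError(f"cyclic set hierarchy at {node!r}")
                    seen.add(node)

    def names(self) -> list[str]:
        return sorted(self.sets)


def hypergeom_enrich(
    module_genes,
    sets: GeneSetCollection,
    universe=None,
    module_id: int | str = 1,
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``module_genes`` in each set.

    With universe size N, set size K, module size n and overlap k, the
    p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n). Set
    members outside the universe are dropped (counted in a warning); BH
    adjustment is across all sets for this module.
    """
    if universe is None:
        universe = sets.universe
    if universe is None:
        raise ValueError("a gene universe is required")
    universe = set(universe)
    module = set(module_genes)
    outside = module - universe
    if outside:
        raise ValueError(
            f"{len(outside)} module genes outside the universe (e.g. {sorted(outside)[:3]})"
        )
    N, n = len(universe), len(module)
    rows = []
    dropped = 0
    for name in sets.names():
        members = sets.sets[name] & universe
        dropped += len(sets.sets[name]) - len(members)
        K = len(members)
        k = len(module & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"module": module_id, "set": name, "k": k, "n": n, "K": K, "N": N,
                     "p": min(p, 1.0)})
    if dropped:
        logger.warning("%d gene-set members outside the universe were dropped", dropped)
    df = pd.DataFrame(rows)
    if not df.empty and adjust:
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    elif not df.empty:
        df["fdr"] = df["p"]
    return df


def enrich_modules(
    partition,
    sets: GeneSetCollection,
    universe=None,
    bh_scope: str = "within_module",
) -> pd.DataFrame:
    """Run hypergeometric enrichment for every module of a partition.

    ``bh_scope`` controls whether BH is applied within each module (default)
    or across every (module, set) test jointly.
    """
    frames = []
    universe = set(universe) if universe is not None else sets.universe
    for mid, members in sorted(partition.modules().items()):
        mem = members & universe if universe else members
        if not mem:
            continue
        frames.append(
            hypergeom_enrich(mem, sets, universe=universe, module_id=mid,
                             adjust=(bh_scope == "within_module"))
        )
    if not frames:
        return pd.DataFrame(columns=["module", "set", "k", "n", "K", "N", "p", "fdr"])
    df = pd.concat(frames, ignore_index=True)
    if bh_scope == "global":
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df


def overlap_coefficient(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def build_enrichment_map(
    rows: pd.DataFrame,
    sets: GeneSetCollection,
    fdr_cutoff: float = 0.001,
    overlap_cutoff: float = 0.5,
) -> nx.DiGraph:
    """Enrichment map over significant sets (fdr < cutoff).

    Directed parent -> child edges come from the collection hierarchy when
    present; otherwise undirected-style reciprocal links are drawn between
    sets whose overlap coefficient |A∩B| / min(|A|,|B|) meets the cutoff.
    Node attribute ``size`` is the member count.
    """
    g = nx.DiGraph()
    if rows.empty:
        return g
    significant = sorted(set(rows.loc[rows["fdr"] < fdr_cutoff, "set"]))
    for name in significant:
        g.add_node(name, size=len(sets.sets[name]))
    if sets.parent_of:
        for child in significant:
            parent = sets.parent_of.get(child)
            if parent in g:
                g.add_edge(parent, child, kind="hierarchy")
    else:
        for i, a in enumerate(significant):
            for b in significant[i + 1:]:
                oc = overlap_coefficient(sets.sets[a], sets.sets[b])
                if oc >= overlap_cutoff:
                    g.add_edge(a, b, kind="overlap", overlap=oc)
                    g.add_edge(b, a, kind="overlap", overlap=oc)
    return g


def enrichment_score(
    scores: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Running-sum enrichment score of a set along a ranked list.

    Hits increment proportionally to |score|^weight (normalized over in-set
    genes), misses decrement by 1/(N-K); ES is the maximal deviation from
    zero, returned with the index where the extremum is attained.
    """
    scores = np.asarray(scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    N, K = len(scores), int(in_set.sum())
    if K == 0:
        raise ValueError("set has no members in the ranked list")
    if K == N:  # no misses: the running sum climbs monotonically to 1
        return 1.0, N - 1
    w = np.abs(scores) ** weight
    hit_mass = np.where(in_set, w, 0.0)
    total = hit_mass.sum()
    if total == 0:  # all in-set scores zero: fall back to unweighted hits
        hit_mass = in_set.astype(float)
        total = hit_mass.sum()
    running = np.cumsum(hit_mass / total - (~in_set) / (N - K))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


@dataclass
class _SetResult:
    name: str
    es: float
    peak: int
    leading_edge: list[str]


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked GSEA over a score-ordered gene list.

    ``ranked`` maps genes (index, unique, already ordered best-to-worst) to
    ranking scores. The null distribution permutes gene labels (random
    same-size subsets of the list); NES divides ES by the mean |null ES| of
    the same sign, the permutation p is the same-sign null tail, and FDR
    follows the standard NES-based procedure. Sets with fewer than
    ``min_size`` members in the list are skipped.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list must contain unique genes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    present = set(genes)
    rng = np.random.default_rng(seed)

    observed: list[_SetResult] = []
    null_by_set: dict[str, np.ndarray] = {}
    for name in sets.names():
        members = sets.sets[name] & present
        K = len(members)
        if K < min_size or K >= len(genes):
            logger.warning("set %s skipped (%d usable members)", name, K)
            continue
        in_set = np.isin(genes, sorted(members))
        es, peak = enrichment_score(scores, in_set, weight)
        if es >= 0:
            le = [g for g, m in zip(genes[: peak + 1], in_set[: peak + 1]) if m]
        else:
            le = [g for g, m in zip(genes[peak:], in_set[peak:]) if m]
        observed.append(_SetResult(name, es, peak, le))
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=K, replace=False)] = True
            null[i], _ = enrichment_score(scores, perm, weight)
        null_by_set[name] = null

    if not observed:
        return pd.DataFrame(columns=["set", "es", "nes", "p_perm", "fdr", "leading_edge"])

    def _nes(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.mean(np.abs(same)) if same.size else np.mean(np.abs(null))
        return es / denom if denom > 0 else 0.0

    rows = []
    all_null_nes = np.concatenate(
        [np.array([_nes(v, null_by_set[r.name]) for v in null_by_set[r.name]])
         for r in observed]
    )
    obs_nes = {r.name: _nes(r.es, null_by_set[r.name]) for r in observed}
    for r in observed:
        null = null_by_set[r.name]
        if r.es >= 0:
            pos = null[null >= 0]
            p = float(np.mean(pos >= r.es)) if pos.size else 0.0
        else:
            neg = null[null < 0]
            p = float(np.mean(neg <= r.es)) if neg.size else 0.0
        nes = obs_nes[r.name]
        if nes >= 0:
            num_den = np.mean(all_null_nes[all_null_nes >= 0] >= nes) if np.any(all_null_nes >= 0) else 0.0
            obs_frac = np.mean([v >= nes for v in obs_nes.values() if v >= 0] or [1.0])
        else:
            num_den = np.mean(all_null_nes[all_null_nes < 0] <= nes) if np.any(all_null_nes < 0) else 0.0
            obs_frac = np.mean([v <= nes for v in obs_nes.values() if v < 0] or [1.0])
        fdr = min(1.0, num_den / obs_frac) if obs_frac > 0 else 1.0
        rows.append({"set": r.name, "es": r.es, "nes": nes, "p_perm": p,
                     "fdr": fdr, "leading_edge": ",".join(r.leading_edge)})
    return pd.DataFrame(rows)
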