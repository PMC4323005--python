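"""Synthetic study generator.

Emulates the full input bundle of the differential-network pipeline with
known ground truth: an RNA-seq-like negative-binomial count matrix with
planted differentially expressed genes and planted sample subtypes, a
reference interactome with dense planted communities joined by bridge
(bottleneck) nodes, gene sets matching the planted communities plus decoys,
a drug-target table containing one planted multi-target drug that covers
the planted bridges (and the Dasatinib catalog record), and limiting-
dilution experiments simulated under the single-hit model.

Design choices: counts are negative binomial with a log-normal baseline and
shared dispersion (standard RNA-seq overdispersion); the interactome is a
planted-partition graph whose communities touch only through explicitly
inserted bridge nodes, so the betweenness ground truth is unambiguous. Each
generator draws from its own seeded RNG stream, so any input can be
regenerated in isolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugs import DrugTargetTable, dasatinib_records
from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .lda import LDAExperiment
from .network import Interactome

# distinct RNG streams per generator
_STREAM_EXPRESSION = 1
_STREAM_INTERACTOME = 2
_STREAM_GENESETS = 3
_STREAM_DRUGS = 4

PARENT_SET_NAME = "planted_modules"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of the synthetic scenario."""

    n_genes: int = 600
    samples_per_condition: int = 6
    n_conditions: int = 2
    n_de_genes: int = 120
    planted_log2fc: float = 2.0
    dispersion: float = 0.1
    n_subtypes: int = 3
    n_communities: int = 3
    community_size: int = 8
    n_bridges: int = 2
    n_drugs: int = 50
    planted_drug_targets: int = 4
    seed: int = 0
    # nuisance parameters of the emulation, not part of the core design
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.0
    subtype_log2_boost: float = 1.5
    within_community_p: float = 0.9
    bridge_anchors: int = 3

    def validate(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "samples_per_condition": self.samples_per_condition,
            "n_conditions": self.n_conditions,
            "n_subtypes": self.n_subtypes,
            "n_communities": self.n_communities,
            "community_size": self.community_size,
            "n_drugs": self.n_drugs,
            "dispersion": self.dispersion,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.n_de_genes < 0 or self.n_bridges < 0 or self.planted_drug_targets < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.samples_per_condition < 2:
            raise ValueError("need at least 2 samples per condition")
        max_pairs = self.n_communities * (self.n_communities - 1) // 2
        if self.n_bridges > max_pairs:
            raise ValueError(
                f"n_bridges={self.n_bridges} exceeds community pairs ({max_pairs})"
            )


@dataclass
class GroundTruth:
    """Planted structure shared by the generators."""

    de_gene_ids: set[str] = field(default_factory=set)
    up_gene_ids: set[str] = field(default_factory=set)
    subtype_of_sample: dict[str, int] = field(default_factory=dict)
    community_of_node: dict[str, int] = field(default_factory=dict)
    bridge_nodes: set[str] = field(default_factory=set)
    hub_nodes: list[str] = field(default_factory=list)
    planted_drug_id: str = ""

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            de_gene_ids=self.de_gene_ids | other.de_gene_ids,
            up_gene_ids=self.up_gene_ids | other.up_gene_ids,
            subtype_of_sample={**self.subtype_of_sample, **other.subtype_of_sample},
            community_of_node={**self.community_of_node, **other.community_of_node},
            bridge_nodes=self.bridge_nodes | other.bridge_nodes,
            hub_nodes=self.hub_nodes or other.hub_nodes,
            planted_drug_id=self.planted_drug_id or other.planted_drug_id,
        )


def gene_ids(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec_seed])


def gen_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts with planted DE genes and subtype blocks.

    The first ``n_de_genes`` genes are differential between the first
    (reference) condition and every other condition: the first half shifted
    up by ``planted_log2fc`` log2 units, the rest down. Up-genes are split
    into subtype blocks; samples carry a round-robin subtype whose block
    genes get an extra ``subtype_log2_boost`` so consensus NMF can recover
    the subtypes from the signature matrix.
    """
    spec.validate()
    rng = _rng(spec.seed, _STREAM_EXPRESSION)

    genes = gene_ids(spec)
    conditions = [f"cond{i + 1}" for i in range(spec.n_conditions)]
    samples, cond_of = [], {}
    for cond in conditions:
        for j in range(spec.samples_per_condition):
            s = f"{cond}_s{j + 1}"
            samples.append(s)
            cond_of[s] = cond

    de = genes[: spec.n_de_genes]
    n_up = (len(de) + 1) // 2
    up, down = de[:n_up], de[n_up:]

    base = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes))
    mu = np.tile(base[:, None], (1, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    case_cols = np.array([j for j, s in enumerate(samples) if cond_of[s] != conditions[0]])
    if len(case_cols):
        up_rows = [gene_pos[g] for g in up]
        down_rows = [gene_pos[g] for g in down]
        mu[np.ix_(up_rows, case_cols)] *= 2.0 ** spec.planted_log2fc
        mu[np.ix_(down_rows, case_cols)] *= 2.0 ** (-spec.planted_log2fc)

    subtype_of = {s: (i % spec.n_subtypes) + 1 for i, s in enumerate(samples)}
    blocks: dict[int, list[str]] = {k: [] for k in range(1, spec.n_subtypes + 1)}
    for i, g in enumerate(up):
        blocks[(i % spec.n_subtypes) + 1].append(g)
    for st, block in blocks.items():
        cols = [j for j, s in enumerate(samples) if subtype_of[s] == st]
        rows = [gene_pos[g] for g in block]
        if rows and cols:
            mu[np.ix_(rows, cols)] *= 2.0 ** spec.subtype_log2_boost

    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    truth = GroundTruth(
        de_gene_ids=set(de), up_gene_ids=set(up), subtype_of_sample=subtype_of
    )
    return ExpressionMatrix(genes, samples, counts, cond_of), truth


def _sample_edge_attrs(rng: np.random.Generator) -> dict:
    provenance = "pathway" if rng.random() < 0.7 else "predicted"
    directed = bool(rng.random() < 0.5)
    if directed:
        effect = str(rng.choice(
            ["activation", "expression_regulation", "catalysis", "inhibition"]
        ))
    else:
        effect = "unknown"
    return {"provenance": provenance, "directed": directed, "effect": effect}


def gen_interactome(spec: SyntheticSpec) -> tuple[Interactome, GroundTruth]:
    """Planted-partition interactome with explicit bridge nodes.

    Communities are dense (spanning cycle plus random edges at
    ``within_community_p``) and share no direct edges; each bridge node is
    the unique articulation path between one community pair, wired to a few
    anchor nodes on each side, so it attains the maximal betweenness.
    Community members and bridges are drawn from the up-regulated planted
    DE genes, so the induced case network contains the planted graph.
    """
    spec.validate()
    if spec.community_size < 3:
        raise ValueError("community_size must be >= 3")
    rng = _rng(spec.seed, _STREAM_INTERACTOME)

    genes = gene_ids(spec)
    n_up = (spec.n_de_genes + 1) // 2
    pool = genes[:n_up]
    needed = spec.n_communities * spec.community_size + spec.n_bridges
    if needed > len(pool):
        raise ValueError(
            f"spec needs {needed} up-regulated genes for the interactome but "
            f"only {len(pool)} are planted; modules cannot be connected as requested"
        )

    inter = Interactome()
    community_of: dict[str, int] = {}
    idx = 0
    members: dict[int, list[str]] = {}
    for c in range(1, spec.n_communities + 1):
        mem = pool[idx: idx + spec.community_size]
        idx += spec.community_size
        members[c] = mem
        for node in mem:
            community_of[node] = c
        # spanning cycle keeps the module connected
        for i in range(len(mem)):
            inter.add(mem[i], mem[(i + 1) % len(mem)], **_sample_edge_attrs(rng))
        for u, v in itertools.combinations(mem, 2):
            if not inter.edge_keys & {(min(u, v), max(u, v), p) for p in
                                      ("pathway", "predicted", "unknown")}:
                if rng.random() < spec.within_community_p:
                    inter.add(u, v, **_sample_edge_attrs(rng))

    bridges: set[str] = set()
    pairs = list(itertools.combinations(range(1, spec.n_communities + 1), 2))
    for b in range(spec.n_bridges):
        node = pool[idx]
        idx += 1
        c1, c2 = pairs[b]
        bridges.add(node)
        community_of[node] = c1
        n_anchor = min(spec.bridge_anchors, spec.community_size)
        for c in (c1, c2):
            anchors = rng.choice(members[c], size=n_anchor, replace=False)
            for a in anchors:
                inter.add(node, str(a), **_sample_edge_attrs(rng))

    # background: sparse random interactions over down-regulated and non-DE
    # genes, so the reference covers genes outside the planted case modules
    # and the opposite condition induces a (less structured) network too
    n_down = spec.n_de_genes - n_up
    down = genes[n_up: spec.n_de_genes]
    others = genes[spec.n_de_genes: spec.n_de_genes + max(0, 2 * n_down)]
    if len(down) >= 2:
        for i in range(len(down) - 1):  # spanning path keeps them connected
            inter.add(down[i], down[i + 1], **_sample_edge_attrs(rng))
        p_bg = min(1.0, 2.0 / max(1, len(down) - 1))
        for u, v in itertools.combinations(down, 2):
            if rng.random() < p_bg:
                inter.add(u, v, **_sample_edge_attrs(rng))
        for o in others:
            if rng.random() < 0.3:
                inter.add(o, str(rng.choice(down)), **_sample_edge_attrs(rng))

    # hub ground truth lives on the case subgraph (planted modules+bridges):
    # that is the network the planted multi-target drug must cover
    case = inter.graph().subgraph(community_of)
    deg = dict(case.degree())
    n_hubs = max(1, int(0.1 * len(deg)))
    hubs = sorted(deg, key=lambda v: (-deg[v], v))[:n_hubs]
    truth = GroundTruth(
        community_of_node=community_of, bridge_nodes=bridges, hub_nodes=hubs
    )
    return inter, truth


def gen_genesets(
    truth: GroundTruth,
    spec: SyntheticSpec | None = None,
    n_decoys: int = 5,
    seed: int | None = None,
) -> GeneSetCollection:
    """One exact gene set per planted community, plus size-matched decoy
    sets drawn uniformly from the universe, under a single parent set."""
    if not truth.community_of_node:
        raise ValueError("ground truth has no planted communities")
    if seed is None:
        seed = spec.seed if spec is not None else 0
    rng = _rng(seed, _STREAM_GENESETS)

    if spec is not None:
        universe = set(gene_ids(spec))
    else:
        universe = set(truth.community_of_node) | truth.de_gene_ids
    sets: dict[str, set[str]] = {}
    parent_of: dict[str, str] = {}
    sizes = []
    for c in sorted(set(truth.community_of_node.values())):
        name = f"community_{c}"
        sets[name] = {n for n, cc in truth.community_of_node.items() if cc == c}
        parent_of[name] = PARENT_SET_NAME
        sizes.append(len(sets[name]))
    sets[PARENT_SET_NAME] = set().union(*sets.values())
    pool = sorted(universe)
    for i in range(n_decoys):
        size = sizes[i % len(sizes)]
        sets[f"decoy_{i + 1}"] = set(rng.choice(pool, size=size, replace=False))
    return GeneSetCollection(sets=sets, universe=universe, parent_of=parent_of)


def gen_drug_table(truth: GroundTruth, spec: SyntheticSpec) -> tuple[DrugTargetTable, GroundTruth]:
    """Drug-target table: one planted multi-target drug covering the planted
    bridge/hub nodes, uniform decoy drugs, and the Dasatinib catalog record."""
    spec.validate()
    if spec.planted_drug_targets < 1:
        raise ValueError("planted_drug_targets must be >= 1")
    rng = _rng(spec.seed, _STREAM_DRUGS)

    eligible = sorted(truth.bridge_nodes) + [
        h for h in truth.hub_nodes if h not in truth.bridge_nodes
    ]
    if spec.planted_drug_targets > len(eligible):
        raise ValueError(
            f"planted_drug_targets={spec.planted_drug_targets} exceeds the "
            f"{len(eligible)} planted bridge+hub nodes"
        )
    planted_id = "D0001"
    records = [
        (planted_id, "PlantedMultiTKI", t)
        for t in eligible[: spec.planted_drug_targets]
    ]
    proteins = sorted(truth.community_of_node) or sorted(truth.de_gene_ids)
    for i in range(2, spec.n_drugs + 1):
        n_t = int(rng.integers(1, 4))
        targets = rng.choice(proteins, size=min(n_t, len(proteins)), replace=False)
        for t in targets:
            records.append((f"D{i:04d}", f"Decoy{i:04d}", str(t)))
    records.extend(dasatinib_records())
    table = DrugTargetTable.from_records(records)
    return table, replace_truth_drug(truth, planted_id)


def replace_truth_drug(truth: GroundTruth, drug_id: str) -> GroundTruth:
    out = GroundTruth(**{**truth.__dict__})
    out.planted_drug_id = drug_id
    return out


def gen_lda_data(
    true_frequency: float,
    doses=(1_000_000, 100_000, 10_000, 1_000),
    replicates_per_dose: int = 10,
    seed: int = 0,
) -> LDAExperiment:
    """Simulated serial-dilution experiment under the single-hit model: an
    injection of d cells is positive with probability 1 - exp(-f * d)."""
    if not 0 < true_frequency < 1:
        raise ValueError("true_frequency must lie in (0, 1)")
    doses = list(doses)
    if not doses or any(d <= 0 for d in doses):
        raise ValueError("doses must be a nonempty list of positive integers")
    if replicates_per_dose < 1:
        raise ValueError("replicates_per_dose must be positive")
    rng = np.random.default_rng([5, seed])
    rows = []
    for d in doses:
        p_pos = -math.expm1(-true_frequency * d)
        pos = int(rng.binomial(replicates_per_dose, p_pos))
        rows.append({"dose": d, "injected": replicates_per_dose, "positive": pos})
    return LDAExperiment(pd.DataFrame(rows))


@dataclass
class Scenario:
    """A fully generated synthetic study."""

    spec: SyntheticSpec
    expression: ExpressionMatrix
    interactome: Interactome
    genesets: GeneSetCollection
    drugs: DrugTargetTable
    truth: GroundTruth


def generate_scenario(spec: SyntheticSpec) -> Scenario:
    """Generate every pipeline input for one spec, with merged ground truth."""
    expr, t1 = gen_expression(spec)
    inter, t2 = gen_interactome(spec)
    truth = t1.merge(t2)
    genesets = gen_genesets(truth, spec)
    drugs, truth = gen_drug_table(truth, spec)
    return Scenario(spec, expr, inter, genesets, drugs, truth)
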