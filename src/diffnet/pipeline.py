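"""End-to-end orchestration: differential expression -> signature ->
consensus-NMF subtyping -> condition networks -> subtraction -> modules,
enrichment and GSEA -> bottleneck/hub ranking -> drug repositioning ->
optional limiting-dilution analysis.

Every stage writes its outputs before the next starts, so a failure in
stage k leaves stages < k on disk together with a partial manifest; the
whole run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .centrality import rank_bottlenecks_hubs
from .communities import edge_betweenness_communities
from .config import PipelineConfig, dump_config
from .drugs import build_dtn, score_drugs
from .enrichment import build_enrichment_map, enrich_modules, gsea_preranked
from .expression import de_test, filter_signature, normalize_counts
from .io import (
    read_drug_table,
    read_expression,
    read_gmt,
    read_interactome,
    read_lda,
    write_drug_table,
    write_edge_tsv,
    write_expression,
    write_gmt,
    write_lda,
    write_sif,
)
from .lda import compare_frequencies, estimate_frequency
from .network import induce_condition_network, subtract_networks
from .nmf import scale_rows_unit_max, select_k
from .synth import SyntheticSpec, gen_lda_data, generate_scenario

logger = logging.getLogger(__name__)

STAGES = ("load", "de", "signature", "nmf", "network", "subtract",
          "modules", "enrich", "gsea", "centrality", "drugs", "lda")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    version: str = __version__
    seed: int = 0
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _hash_config(cfg: PipelineConfig) -> str:
    payload = asdict(cfg)
    payload.pop("outdir", None)  # where outputs land does not change them
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=list).encode()
    ).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage in order, writing outputs under ``cfg.outdir``."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(cfg),
        seed=cfg.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    dump_config(cfg, out / "config.yaml")
    manifest_path = out / "manifest.json"

    state: dict = {}

    def _run(stage: str, fn) -> None:
        try:
            fn()
        except Exception as err:
            manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
            manifest.write(manifest_path)
            raise StageError(stage, err) from err
        manifest.completed_stages.append(stage)

    def load() -> None:
        for key in ("expression", "conditions", "interactome", "gene_sets", "drug_table"):
            p = getattr(cfg, key)
            if p:
                manifest.input_checksums[key] = _file_checksum(p)
        for key in ("lda_case", "lda_reference"):
            if getattr(cfg, key):
                manifest.input_checksums[key] = _file_checksum(getattr(cfg, key))
        state["expr"] = read_expression(cfg.expression, cfg.conditions)
        state["inter"] = read_interactome(cfg.interactome)
        state["sets"] = read_gmt(cfg.gene_sets)
        state["drugs"] = read_drug_table(cfg.drug_table)
        manifest.stage_counts["load"] = {
            "genes": len(state["expr"].gene_ids),
            "samples": len(state["expr"].sample_ids),
            "interactome_nodes": len(state["inter"].nodes),
            "interactome_edges": state["inter"].n_edges,
            "gene_sets": len(state["sets"].sets),
            "drugs": len(state["drugs"].drug_ids),
        }

    def de() -> None:
        expr = state["expr"]
        norm = normalize_counts(expr, cfg.normalization)
        state["norm"] = norm
        conditions = expr.conditions
        ref = conditions[0]
        tables = {}
        for cond in conditions[1:]:
            res = de_test(
                norm, ref, cond, test=cfg.de_test, pseudocount=cfg.pseudocount,
                fc_threshold=cfg.fc_threshold, p_threshold=cfg.p_threshold,
                seed=cfg.seed,
            )
            res.to_csv(out / f"de_{cond}_vs_{ref}.tsv", sep="\t")
            tables[cond] = res
        state["de"] = tables
        manifest.stage_counts["de"] = {
            c: int(t["passes_filter"].sum()) for c, t in tables.items()
        }

    def signature() -> None:
        genes = filter_signature(
            list(state["de"].values()), cfg.fc_threshold, cfg.p_threshold
        )
        state["signature"] = genes
        (out / "signature.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
        manifest.stage_counts["signature"] = {"genes": len(genes)}

    def nmf() -> None:
        genes = state["signature"]
        if not genes:
            manifest.stage_counts["nmf"] = {"skipped": "empty signature"}
            return
        norm = state["norm"].subset_genes(genes)
        # subtypes live among the tumor samples: cluster the non-reference
        # conditions; fall back to all samples when too few remain
        ref_cond = norm.conditions[0]
        case_samples = [s for s in norm.sample_ids
                        if norm.condition_of_sample[s] != ref_cond]
        if len(case_samples) < 4:
            case_samples = list(norm.sample_ids)
        cols = norm.column_indices(case_samples)
        V = scale_rows_unit_max(norm.counts[:, cols])
        k_hi = min(cfg.k_max, len(case_samples) - 1)
        sel = select_k(
            V, range(cfg.k_min, k_hi + 1), n_runs=cfg.nmf_runs, seed=cfg.seed,
            sample_ids=case_samples,
        )
        state["k_selection"] = sel
        sel.table.to_csv(out / "nmf_cophenetic.tsv", sep="\t")
        best = sel.results[sel.best_k]
        best.consensus_frame().to_csv(out / f"consensus_k{sel.best_k}.tsv", sep="\t")
        pd.Series(best.labels, name="cluster").rename_axis("sample").to_csv(
            out / "nmf_labels.tsv", sep="\t"
        )
        manifest.stage_counts["nmf"] = {
            "selected_k": sel.best_k,
            "cophenetic": float(best.cophenetic),
            "samples_clustered": len(case_samples),
        }

    def network() -> None:
        inter, tables = state["inter"], state["de"]
        first = next(iter(tables))
        de_tab = tables[first]
        sig = set(state["signature"])
        if cfg.network_mode == "full_signature" or len(tables) >= 2:
            if len(tables) >= 2:
                conds = list(tables)[:2]
                members = {
                    c: set(filter_signature(tables[c], cfg.fc_threshold, cfg.p_threshold))
                    for c in conds
                }
                net_a = induce_condition_network(inter, members[conds[0]],
                                                 tables[conds[0]], conds[0])
                net_b = induce_condition_network(inter, members[conds[1]],
                                                 tables[conds[1]], conds[1])
            else:
                net_a = induce_condition_network(inter, sig, de_tab, first)
                net_b = net_a
        else:
            up = {g for g in sig if de_tab.loc[g, "log2fc"] > 0}
            down = {g for g in sig if de_tab.loc[g, "log2fc"] < 0}
            net_a = induce_condition_network(inter, up, de_tab, f"{first}_up")
            net_b = induce_condition_network(inter, down, de_tab, f"{first}_down")
        state["net_a"], state["net_b"] = net_a, net_b
        manifest.stage_counts["network"] = {
            "nodes_a": net_a.graph.number_of_nodes(),
            "edges_a": len(net_a.edge_keys),
            "unmapped_a": len(net_a.unmapped_genes),
            "nodes_b": net_b.graph.number_of_nodes(),
            "edges_b": len(net_b.edge_keys),
        }

    def subtract() -> None:
        dn = subtract_networks(state["net_a"], state["net_b"])
        state["diff"] = dn
        for name, keys in (("unique_a", dn.unique_a), ("unique_b", dn.unique_b),
                           ("shared", dn.shared)):
            pd.DataFrame(sorted(keys), columns=["source", "target", "provenance"]).to_csv(
                out / f"diffnet_{name}.tsv", sep="\t", index=False
            )
        summary = dn.node_summary()
        pd.DataFrame(
            [{"partition": k, "n_nodes": len(v), "nodes": ",".join(sorted(v))}
             for k, v in summary.items()]
        ).to_csv(out / "diffnet_nodes.tsv", sep="\t", index=False)
        manifest.stage_counts["subtract"] = {
            "unique_a": len(dn.unique_a), "unique_b": len(dn.unique_b),
            "shared": len(dn.shared),
        }

    def modules() -> None:
        part = edge_betweenness_communities(state["net_a"].graph)
        state["modules"] = part
        pd.Series(part.module_of_node, name="module").rename_axis("node").sort_index(
        ).to_csv(out / "modules.tsv", sep="\t")
        manifest.stage_counts["modules"] = {
            "n_modules": part.n_modules, "modularity": float(part.modularity),
        }

    def enrich() -> None:
        sets = state["sets"]
        universe = sets.universe or set(state["expr"].gene_ids)
        rows = enrich_modules(state["modules"], sets, universe=universe)
        rows.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        emap = build_enrichment_map(rows, sets, fdr_cutoff=cfg.module_fdr,
                                    overlap_cutoff=cfg.overlap_cutoff)
        nx.write_graphml(emap, out / "enrichment_map.graphml")
        manifest.stage_counts["enrich"] = {
            "tests": len(rows),
            "significant": int((rows["fdr"] < cfg.module_fdr).sum()) if len(rows) else 0,
        }

    def gsea() -> None:
        first = next(iter(state["de"]))
        ranked = state["de"][first]["log2fc"].sort_values(ascending=False)
        res = gsea_preranked(ranked, state["sets"], n_perm=cfg.gsea_permutations,
                             seed=cfg.seed)
        res.to_csv(out / "gsea.tsv", sep="\t", index=False)
        manifest.stage_counts["gsea"] = {"sets_tested": len(res)}

    def centrality() -> None:
        g = state["net_a"].graph
        top_n = min(cfg.top_n_bottlenecks, g.number_of_nodes())
        table = rank_bottlenecks_hubs(g, top_n, cfg.hub_quantile)
        state["centrality"] = table
        table.to_csv(out / "centrality.tsv", sep="\t")
        ua = state["diff"].unique_a_graph()
        if ua.number_of_nodes():
            rank_bottlenecks_hubs(
                ua, min(cfg.top_n_bottlenecks, ua.number_of_nodes()), cfg.hub_quantile
            ).to_csv(out / "centrality_unique_a.tsv", sep="\t")
        manifest.stage_counts["centrality"] = {
            "nodes": g.number_of_nodes(), "top_n": top_n,
        }

    def drugs() -> None:
        dtn = build_dtn(state["drugs"], set(state["net_a"].graph.nodes))
        nx.write_graphml(dtn, out / "dtn.graphml")
        scores = score_drugs(dtn, state["centrality"], state["modules"],
                             weights=tuple(cfg.drug_weights))
        scores.to_csv(out / "drug_ranking.tsv", sep="\t")
        state["drug_scores"] = scores
        manifest.stage_counts["drugs"] = {
            "drugs_in_dtn": int(scores.shape[0]),
            "top_drug": scores.index[0] if len(scores) else "",
        }

    def lda() -> None:
        if not cfg.lda_case:
            manifest.stage_counts["lda"] = {"skipped": "no data"}
            return
        case = read_lda(cfg.lda_case)
        est = estimate_frequency(case)
        result = {
            "frequency": est.frequency, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "boundary_flag": est.boundary_flag,
        }
        if cfg.lda_reference:
            ref = read_lda(cfg.lda_reference)
            comp = compare_frequencies(case, ref)
            result.update({
                "fold_vs_reference": comp.fold,
                "fold_ci_low": comp.fold_ci_low,
                "fold_ci_high": comp.fold_ci_high,
                "p_equal_frequency": comp.p_value,
            })
        with open(out / "lda_estimate.json", "w") as fh:
            json.dump(result, fh, indent=2)
        manifest.stage_counts["lda"] = {"frequency": est.frequency}

    for stage, fn in (("load", load), ("de", de), ("signature", signature),
                      ("nmf", nmf), ("network", network), ("subtract", subtract),
                      ("modules", modules), ("enrich", enrich), ("gsea", gsea),
                      ("centrality", centrality), ("drugs", drugs), ("lda", lda)):
        logger.info("stage %s", stage)
        _run(stage, fn)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(manifest_path)
    return manifest


def write_scenario(spec: SyntheticSpec, outdir, lda_frequencies=(1e-3, 1e-6)) -> dict:
    """Generate a synthetic study and write every pipeline input under
    ``outdir``; returns the paths plus the ground-truth record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scen = generate_scenario(spec)
    paths = {
        "expression": str(out / "expression.tsv"),
        "conditions": str(out / "conditions.tsv"),
        "interactome": str(out / "interactome.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
        "drug_table": str(out / "drug_targets.tsv"),
        "lda_case": str(out / "lda_case.tsv"),
        "lda_reference": str(out / "lda_reference.tsv"),
    }
    write_expression(scen.expression, paths["expression"], paths["conditions"])
    write_edge_tsv(scen.interactome, paths["interactome"])
    write_sif(scen.interactome, out / "interactome.sif")
    write_gmt(scen.genesets, paths["gene_sets"])
    write_drug_table(scen.drugs, paths["drug_table"])
    f_case, f_ref = lda_frequencies
    write_lda(gen_lda_data(f_case, seed=spec.seed), paths["lda_case"])
    write_lda(gen_lda_data(f_ref, seed=spec.seed + 1), paths["lda_reference"])
    truth = {
        "de_gene_ids": sorted(scen.truth.de_gene_ids),
        "up_gene_ids": sorted(scen.truth.up_gene_ids),
        "subtype_of_sample": scen.truth.subtype_of_sample,
        "community_of_node": scen.truth.community_of_node,
        "bridge_nodes": sorted(scen.truth.bridge_nodes),
        "hub_nodes": list(scen.truth.hub_nodes),
        "planted_drug_id": scen.truth.planted_drug_id,
        "lda_frequencies": list(lda_frequencies),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return {"paths": paths, "truth": truth, "scenario": scen}
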