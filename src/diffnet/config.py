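"""Pipeline configuration: flat YAML/JSON key-value files with validated,
literature-anchored defaults (2.0-fold change at p < 0.05 for the signature,
module-pathway FDR < 0.001, differential-pathway FDR < 0.0001, BH alpha
0.05, 1000 consensus-NMF runs, top-18 bottlenecks)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


@dataclass
class PipelineConfig:
    # input paths
    expression: str = ""
    conditions: str = ""
    interactome: str = ""
    gene_sets: str = ""
    drug_table: str = ""
    lda_case: str = ""
    lda_reference: str = ""
    outdir: str = "results/pipeline"
    # signature thresholds
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    module_fdr: float = 0.001
    diff_fdr: float = 0.0001
    bh_alpha: float = 0.05
    pseudocount: float = 0.5
    de_test: str = "welch_log"
    normalization: str = "median_ratio"
    # consensus NMF
    k_min: int = 2
    k_max: int = 6
    nmf_runs: int = 1000
    # networks
    network_mode: str = "split_by_sign"  # or "full_signature"
    # centrality / drugs
    top_n_bottlenecks: int = 18
    hub_quantile: float = 0.9
    drug_weights: tuple = (3.0, 2.0, 1.0)
    # enrichment / GSEA
    overlap_cutoff: float = 0.5
    gsea_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for key in ("p_threshold", "module_fdr", "diff_fdr", "bh_alpha"):
            v = getattr(self, key)
            if not 0 < v <= 1:
                bad.append(key)
        if self.fc_threshold <= 0:
            bad.append("fc_threshold")
        if self.pseudocount < 0:
            bad.append("pseudocount")
        if not 1 < self.k_min <= self.k_max:
            bad.append("k_min/k_max")
        if self.nmf_runs < 2:
            bad.append("nmf_runs")
        if self.top_n_bottlenecks < 1:
            bad.append("top_n_bottlenecks")
        if not 0 <= self.hub_quantile <= 1:
            bad.append("hub_quantile")
        w = tuple(self.drug_weights)
        if len(w) != 3 or min(w) < 0 or max(w) <= 0:
            bad.append("drug_weights")
        if self.de_test not in {"welch_log", "permutation"}:
            bad.append("de_test")
        if self.normalization not in {"cpm", "median_ratio"}:
            bad.append("normalization")
        if self.network_mode not in {"split_by_sign", "full_signature"}:
            bad.append("network_mode")
        if bad:
            raise ConfigError(f"invalid configuration values for: {', '.join(bad)}")


def load_config(path) -> PipelineConfig:
    """Load a flat YAML/JSON config; missing keys take defaults, unknown
    keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a flat key/value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    if "drug_weights" in data:
        data["drug_weights"] = tuple(data["drug_weights"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    data = asdict(cfg)
    data["drug_weights"] = list(data["drug_weights"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
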