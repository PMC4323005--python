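"""Readers and writers for the pipeline's plain-text formats.

Expression: gene x sample counts TSV plus a two-column condition sidecar.
Gene sets: GMT (name, description, tab-separated members). Interactome: SIF
(node TAB interaction TAB node) with an optional edge-attribute TSV, a
single attributed edge-list TSV, or GraphML. Drug targets and
limiting-dilution tables are simple TSVs.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .aliases import normalize_symbol
from .drugs import DrugTargetTable
from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .lda import LDAExperiment
from .network import Edge, Interactome

# ---------------------------------------------------------------- expression

def write_expression(m: ExpressionMatrix, counts_path, conditions_path) -> None:
    m.to_frame().rename_axis("gene").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": m.sample_ids,
         "condition": [m.condition_of_sample[s] for s in m.sample_ids]}
    ).to_csv(conditions_path, sep="\t", index=False)


def read_expression(counts_path, conditions_path) -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t")
    cond_of = dict(zip(cond["sample"].astype(str), cond["condition"].astype(str)))
    return ExpressionMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        cond_of,
    )


# ------------------------------------------------------------------ gene sets

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(sets=sets, universe=set(universe) if universe else None)


# ---------------------------------------------------------------- interactome

_EDGE_COLUMNS = ["source", "target", "provenance", "directed", "effect"]


def write_sif(inter: Interactome, sif_path, attrs_path=None) -> None:
    """SIF topology plus an optional sidecar TSV carrying edge attributes."""
    with open(sif_path, "w") as fh:
        for e in inter.edges():
            fh.write(f"{e.u}\tFI\t{e.v}\n")
    if attrs_path is not None:
        write_edge_tsv(inter, attrs_path)


def write_edge_tsv(inter: Interactome, path) -> None:
    rows = [
        {"source": e.u, "target": e.v, "provenance": e.provenance,
         "directed": e.directed, "effect": e.effect}
        for e in inter.edges()
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_graphml(inter: Interactome, path) -> None:
    g = nx.MultiDiGraph()
    for e in inter.edges():
        g.add_edge(e.u, e.v, provenance=e.provenance,
                   directed=str(e.directed), effect=e.effect)
    nx.write_graphml(g, path)


def _add_normalized_edge(inter: Interactome, u: str, v: str, provenance: str,
                         directed: bool, effect: str, apply_aliases: bool) -> None:
    nu, nv = normalize_symbol(u, apply_aliases), normalize_symbol(v, apply_aliases)
    inter.add_edge(Edge(nu, nv, provenance, directed, effect, raw_u=u, raw_v=v))


def read_interactome(path, fmt: str | None = None, apply_aliases: bool = True) -> Interactome:
    """Read a reference interactome (``sif``, ``edge_tsv`` or ``graphml``;
    inferred from the extension when ``fmt`` is None). Symbols are
    upper-cased and alias-mapped; duplicate edges merge, attribute conflicts
    are kept as parallel edges."""
    path = Path(path)
    if fmt is None:
        fmt = {".sif": "sif", ".tsv": "edge_tsv", ".graphml": "graphml"}.get(
            path.suffix.lower()
        )
    if fmt not in {"sif", "edge_tsv", "graphml"}:
        raise ValueError(f"unknown interactome format: {fmt!r}")
    inter = Interactome()
    if fmt == "sif":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed SIF line {lineno}")
                _add_normalized_edge(inter, parts[0], parts[2], "unknown",
                                     False, "unknown", apply_aliases)
        attrs = path.with_suffix(".attrs.tsv")
        if attrs.exists():
            # attribute sidecar carries the full attributed edge list
            return read_interactome(attrs, "edge_tsv", apply_aliases)
    elif fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _EDGE_COLUMNS[:2] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            try:
                _add_normalized_edge(
                    inter,
                    str(row.source),
                    str(row.target),
                    str(getattr(row, "provenance", "unknown")),
                    str(getattr(row, "directed", "False")).lower() in {"true", "1"},
                    str(getattr(row, "effect", "unknown")),
                    apply_aliases,
                )
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    else:
        g = nx.read_graphml(path)
        for u, v, data in g.edges(data=True):
            _add_normalized_edge(
                inter, str(u), str(v),
                str(data.get("provenance", "unknown")),
                str(data.get("directed", "False")).lower() in {"true", "1"},
                str(data.get("effect", "unknown")),
                apply_aliases,
            )
    return inter


# ---------------------------------------------------------------- drug tables

def write_drug_table(table: DrugTargetTable, path) -> None:
    out = table.frame[["drug_id", "drug_name", "target_raw"]].rename(
        columns={"target_raw": "target_symbol"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_drug_table(path, apply_aliases: bool = True) -> DrugTargetTable:
    df = pd.read_csv(path, sep="\t")
    required = {"drug_id", "target_symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: drug table needs columns {sorted(required)}")
    if "drug_name" not in df.columns:
        df["drug_name"] = df["drug_id"]
    records = [
        (str(r.drug_id), str(r.drug_name), str(r.target_symbol))
        for r in df.itertuples(index=False)
    ]
    return DrugTargetTable.from_records(records, apply_aliases)


# -------------------------------------------------------------------- LDA

def write_lda(exp: LDAExperiment, path) -> None:
    exp.frame.astype(int).to_csv(path, sep="\t", index=False)


def read_lda(path) -> LDAExperiment:
    return LDAExperiment(pd.read_csv(path, sep="\t"))
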