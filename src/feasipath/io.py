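"""File dialects: TSV tables, GraphML/SIF network exports, JSON path reports.

All formats are plain text.  GraphML round-trips preserve edge annotations by
serializing linking-metabolite tuples as ``;``-joined strings; SIF uses the
same join as the interaction label.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .association import SimilarityNetwork
from .coexpression import SampleCovariates
from .paths import CandidatePath, FeasiblePath, WitnessStep
from .reconstruction import EnzymeGraph, MetabolicReconstruction

__all__ = [
    "write_reconstruction",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_phenotypes",
    "write_phenotypes",
    "write_graphml",
    "read_graphml",
    "write_sif",
    "write_similarity",
    "read_similarity",
    "write_paths_json",
    "read_paths_json",
    "read_seed_file",
]


def write_reconstruction(recon: MetabolicReconstruction, path: str | Path) -> None:
    lines = ["reaction_id\tgenes\tsubstrates\tproducts\treversible"]
    for r in recon.reactions:
        lines.append(
            "\t".join(
                [
                    r.reaction_id,
                    ";".join(sorted(r.genes)),
                    ";".join(sorted(r.substrates)),
                    ";".join(sorted(r.products)),
                    "1" if r.reversible else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dups[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_covariates(path: str | Path) -> SampleCovariates:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = ["batch", "sex", "nationality"]
    extra = [c for c in df.columns if c not in required]
    if extra:
        import logging

        logging.getLogger(__name__).info("ignoring extra covariate columns: %s", extra)
    return SampleCovariates(df[required])


def write_covariates(cov: SampleCovariates, path: str | Path) -> None:
    cov.table.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_phenotypes(block: pd.DataFrame, path: str | Path) -> None:
    block.to_csv(path, sep="\t", index_label="sample")


def write_graphml(g: EnzymeGraph, path: str | Path) -> None:
    out = nx.DiGraph()
    out.add_nodes_from(g.graph.nodes)
    for u, v, data in g.graph.edges(data=True):
        out.add_edge(u, v, linking=";".join(data.get("linking", ())))
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> EnzymeGraph:
    raw = nx.read_graphml(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(raw.nodes)
    for u, v, data in raw.edges(data=True):
        linking = tuple(m for m in data.get("linking", "").split(";") if m)
        g.add_edge(u, v, linking=linking)
    return EnzymeGraph(graph=g, reaction_index={})


def write_sif(g: EnzymeGraph, path: str | Path) -> None:
    lines = []
    for u, v, data in sorted(g.graph.edges(data=True)):
        lines.append(f"{u}\t{';'.join(data.get('linking', ()))}\t{v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_similarity(net: SimilarityNetwork, path: str | Path) -> None:
    net.pairs.to_csv(path, sep="\t", index=False)


def read_similarity(path: str | Path, threshold: float, mode: str = "spls") -> SimilarityNetwork:
    pairs = pd.read_csv(path, sep="\t")
    return SimilarityNetwork(pairs=pairs, threshold=threshold, mode=mode)


def _path_to_dict(p: FeasiblePath) -> dict:
    return {
        "genes": list(p.genes),
        "witness": [
            {
                "gene": s.gene,
                "reaction": s.reaction_id,
                "consumed": s.consumed,
                "produced": s.produced,
                "intra_gene": s.intra_gene,
            }
            for s in p.witness
        ],
    }


def write_paths_json(paths: list[FeasiblePath], path: str | Path, annotations=None) -> None:
    payload = {"paths": [_path_to_dict(p) for p in paths]}
    if annotations is not None:
        payload["annotated"] = annotations
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_paths_json(path: str | Path) -> list[FeasiblePath]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for d in payload["paths"]:
        witness = tuple(
            WitnessStep(
                gene=s["gene"],
                reaction_id=s["reaction"],
                consumed=s["consumed"],
                produced=s["produced"],
                intra_gene=s["intra_gene"],
            )
            for s in d["witness"]
        )
        out.append(FeasiblePath(path=CandidatePath(tuple(d["genes"])), witness=witness))
    return out


def read_seed_file(path: str | Path):
    """Seed TSV: columns ``variable  gene  sign`` -> {variable: SeedSet}."""
    from .paths import SeedSet

    df = pd.read_csv(path, sep="\t", dtype={"variable": str, "gene": str})
    for col in ("variable", "gene"):
        if col not in df.columns:
            raise ValueError(f"seed file missing column {col!r}")
    out = {}
    for var, sub in df.groupby("variable"):
        genes = tuple(sub["gene"])
        signs = (
            {g: int(s) for g, s in zip(sub["gene"], sub["sign"])}
            if "sign" in sub.columns
            else {}
        )
        out[str(var)] = SeedSet(variable=str(var), genes=genes, signs=signs)
    return out
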