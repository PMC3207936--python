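"""End-to-end pipeline: reconstruction -> enzyme graph -> TC network ->
diet associations -> feasible path extraction -> annotation -> enrichment.

Every stage writes its artifact into the output directory and contributes
counts to a JSON run report, so a run is reproducible and auditable from the
report alone.  A single global seed drives all stochastic components
(cross-validation folds, permutations); child seeds are derived
deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import association as assoc
from . import coexpression as coex
from . import enrichment as enrich_mod
from . import io as fio
from . import paths as paths_mod
from . import reconstruction as recon_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run."""

    reconstruction: str
    expression: str
    covariates: str
    phenotypes: str
    output_dir: str
    currency: str | None = None  # None -> shipped default list
    plasma: str | None = None  # optional second block analysed with rCCA
    # filters and graph options
    variance_fraction: float = 0.10
    retain_primary_currency: bool = True
    # coexpression options
    allow_negative: bool = False
    # association options
    n_components: int | None = 3  # None -> Q2-based selection
    max_components: int = 3
    keep_x: int | None = 2  # sparse selection on the diet block per dimension
    keep_y: int | None = None
    threshold: float = 0.7
    rcca_threshold: float = 0.75
    rcca_lambdas: tuple[float, float] = (0.1, 0.1)
    n_permutations: int = 0
    seed_variables: list[str] | None = None
    # path options
    min_edges: int = 3
    all_shortest: bool = False
    keep_prefixes: bool = False
    # enrichment
    gene_sets: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.threshold < 1:
            raise PipelineError("config", f"threshold {self.threshold} outside [0, 1)")
        for name in ("reconstruction", "expression", "covariates", "phenotypes"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise PipelineError("config", f"{name} file not found: {p}")
        for name in ("currency", "plasma", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} file not found: {p}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "seed": cfg.seed, "stages": {}}

    # --- reconstruction and enzyme graph -----------------------------------
    try:
        currency = (
            recon_mod.load_currency_list(cfg.currency)
            if cfg.currency
            else recon_mod.default_currency_list()
        )
        recon = recon_mod.load_reconstruction(cfg.reconstruction, currency=currency)
        recon = recon_mod.expand_reversible(recon)
        graph = recon_mod.build_enzyme_graph(
            recon, retain_primary_currency=cfg.retain_primary_currency
        )
    except (recon_mod.ReconstructionFormatError, ValueError) as exc:
        raise PipelineError("network", str(exc)) from exc
    fio.write_graphml(graph, out / "enzyme_graph.graphml")
    fio.write_sif(graph, out / "enzyme_graph.sif")
    report["stages"]["network"] = recon_mod.graph_summary(graph) | {
        "reactions": len(recon.reactions),
        "metabolites": len(recon.metabolites),
    }

    # --- expression, variance filter, TC network ---------------------------
    try:
        expr = fio.read_expression(cfg.expression)
        cov = fio.read_covariates(cfg.covariates)
        expr = coex.variance_filter(expr, cfg.variance_fraction)
        tc = coex.build_tc_network(graph, expr, cov, allow_negative=cfg.allow_negative)
    except (ValueError, coex.FitError) as exc:
        raise PipelineError("coexpression", str(exc)) from exc
    fio.write_graphml(tc, out / "tc_network.graphml")
    fio.write_sif(tc, out / "tc_network.sif")
    report["stages"]["coexpression"] = {
        "genes_after_filter": int(expr.shape[0]),
        "tc_nodes": tc.n_nodes,
        "tc_edges": tc.n_edges,
    }

    # --- associations ------------------------------------------------------
    try:
        pheno_raw = fio.read_phenotypes(cfg.phenotypes)
        block = assoc.transform_block(pheno_raw)
        dummies = assoc.dummy_code_covariates(cov.aligned(block.samples))
        X = block.data.join(dummies)
        Y = expr.T.loc[block.samples]
        if cfg.n_components is None:
            H, q2 = assoc.select_dimensions(
                X, Y, max_components=cfg.max_components,
                keep_x=cfg.keep_x, keep_y=cfg.keep_y, seed=cfg.seed,
            )
        else:
            H, q2 = cfg.n_components, []
        fit = assoc.spls_fit(X, Y, n_components=H, keep_x=cfg.keep_x, keep_y=cfg.keep_y)
        net = assoc.similarity_network(fit, threshold=cfg.threshold, X=X, Y=Y)
    except ValueError as exc:
        raise PipelineError("association", str(exc)) from exc
    fio.write_similarity(net, out / "similarity_spls.tsv")
    report["stages"]["association"] = {
        "dimensions": H,
        "q2": [round(v, 6) for v in q2],
        "pairs": int(len(net.pairs)),
        "genes": len(net.genes),
        "transforms": block.transforms,
    }
    overlays = {"diet": net}

    if cfg.plasma:
        plasma_block = assoc.transform_block(fio.read_phenotypes(cfg.plasma))
        Xp = plasma_block.data.join(dummies)
        rfit = assoc.rcca_fit(
            Xp, Y, cfg.rcca_lambdas[0], cfg.rcca_lambdas[1],
            n_components=min(cfg.max_components, Xp.shape[1]),
        )
        rnet = assoc.similarity_network(rfit, threshold=cfg.rcca_threshold, X=Xp, Y=Y)
        fio.write_similarity(rnet, out / "similarity_rcca.tsv")
        overlays["plasma"] = rnet
        report["stages"]["association"]["plasma_pairs"] = int(len(rnet.pairs))

    if cfg.n_permutations > 0:
        focal = cfg.seed_variables[0] if cfg.seed_variables else None
        null = assoc.permutation_null(
            X, Y, n_permutations=cfg.n_permutations, threshold=cfg.threshold,
            seed=cfg.seed, focal_variable=focal,
        )
        (out / "permutation_null.json").write_text(json.dumps(null, indent=2) + "\n")
        report["stages"]["permutation"] = {
            "mean": null["mean"], "median": null["median"], "R": cfg.n_permutations,
        }

    # --- seeds and path extraction -----------------------------------------
    variables = cfg.seed_variables or sorted(net.pairs["variable"].unique())
    all_paths: list[paths_mod.FeasiblePath] = []
    seeds_used: dict[str, list[str]] = {}
    for var in variables:
        genes = tuple(net.genes_for(var))
        if not genes:
            continue
        signs = {
            r.gene: int(r.sign)
            for r in net.pairs[net.pairs["variable"] == var].itertuples()
        }
        seed_set = paths_mod.SeedSet(variable=var, genes=genes, signs=signs)
        found = paths_mod.extract_diet_sensitive_paths(
            tc, recon, seed_set,
            min_edges=cfg.min_edges,
            all_shortest=cfg.all_shortest,
            keep_prefixes=cfg.keep_prefixes,
        )
        seeds_used[var] = sorted(seed_set.restricted_to(tc.graph.nodes).genes)
        all_paths.extend(p for p in found if p.genes not in {q.genes for q in all_paths})
    annotated = paths_mod.annotate_paths(all_paths, overlays)
    fio.write_paths_json(all_paths, out / "paths.json", annotations=annotated)
    if not cfg.all_shortest:
        forest = paths_mod.collapse_to_forest(all_paths) if all_paths else None
        report["stages"]["paths"] = {
            "seeds": seeds_used,
            "n_paths": len(all_paths),
            "forest_nodes": forest.n_nodes if forest else 0,
            "forest_edges": forest.n_edges if forest else 0,
        }
    else:
        report["stages"]["paths"] = {"seeds": seeds_used, "n_paths": len(all_paths)}
    report["paths"] = [list(p.genes) for p in all_paths]

    # --- enrichment --------------------------------------------------------
    if cfg.gene_sets:
        collection = enrich_mod.read_gmt(cfg.gene_sets, universe=expr.index)
        selected = set(net.genes)
        table = enrich_mod.hypergeometric_enrichment(selected, collection)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["enrichment"] = {
            "terms": int(len(table)),
            "min_p": float(table["p_value"].min()) if len(table) else None,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d paths", len(all_paths))
    return report
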