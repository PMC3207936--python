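"""Shortest-path extraction and metabolic feasibility checking.

A connected gene path in the enzyme graph does not guarantee an unbroken chain
of metabolite conversion: gene B may consume A's product in one reaction while
producing C's substrate in an unrelated one.  The feasibility checker performs
a layered reachability pass along the path.  The live set after the seed is
the seed's (currency-filtered) products; at each subsequent gene the live set
becomes the products of reactions consuming a live metabolite, optionally
extended by ONE intra-gene conversion — a second reaction of the same gene
consuming a first-stage product.  The path is feasible iff the live set is
nonempty after the last gene; back-pointers reconstruct a witness conversion
chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .reconstruction import EnzymeGraph, MetabolicReconstruction, Reaction

__all__ = [
    "CandidatePath",
    "WitnessStep",
    "FeasiblePath",
    "FeasibilityResult",
    "PathForest",
    "SeedSet",
    "shortest_paths",
    "check_feasibility",
    "extract_diet_sensitive_paths",
    "collapse_to_forest",
    "annotate_paths",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidatePath:
    """An ordered gene path (seed first) whose consecutive pairs are TC edges."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"repeated genes in path {self.genes}")

    @property
    def n_edges(self) -> int:
        return len(self.genes) - 1

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.genes[:-1], self.genes[1:]))


@dataclass(frozen=True)
class WitnessStep:
    """One conversion step: ``gene``'s ``reaction`` turns ``consumed`` into ``produced``.

    ``consumed`` is None only for the seed's initiating reaction; ``intra_gene``
    marks the single allowed second conversion within one gene.
    """

    gene: str
    reaction_id: str
    consumed: str | None
    produced: str
    intra_gene: bool = False


@dataclass(frozen=True)
class FeasiblePath:
    path: CandidatePath
    witness: tuple[WitnessStep, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return self.path.genes

    @property
    def conversion_chain(self) -> tuple[str, ...]:
        """Metabolite sequence realized by the witness (seed product first)."""
        return (self.witness[0].produced,) + tuple(s.produced for s in self.witness[1:])

    @property
    def linking_chain(self) -> tuple[str, ...]:
        """Metabolites handed across gene boundaries (the inter-gene links)."""
        return tuple(s.consumed for s in self.witness if not s.intra_gene and s.consumed is not None)


@dataclass(frozen=True)
class FeasibilityResult:
    feasible: bool
    path: CandidatePath
    feasible_path: FeasiblePath | None = None
    max_feasible_prefix: tuple[str, ...] = ()


@dataclass(frozen=True)
class SeedSet:
    """Seed genes (with association sign) for one phenotype variable."""

    variable: str
    genes: tuple[str, ...]
    signs: dict[str, int] = field(default_factory=dict)

    def restricted_to(self, nodes) -> "SeedSet":
        nodes = set(nodes)
        kept = tuple(g for g in self.genes if g in nodes)
        dropped = [g for g in self.genes if g not in nodes]
        if dropped:
            logger.info(
                "seed set %s: dropping %d genes absent from network: %s",
                self.variable, len(dropped), dropped[:5],
            )
        return SeedSet(self.variable, kept, {g: s for g, s in self.signs.items() if g in nodes})


def _bfs_parents(tc: EnzymeGraph, seed: str) -> dict[str, str]:
    """Deterministic unit-weight shortest-path tree: the parent of each node is
    the lexicographically smallest gene among its shortest-distance predecessors."""
    dist = {seed: 0}
    parents: dict[str, str] = {}
    frontier = [seed]
    d = 0
    while frontier:
        next_candidates: dict[str, str] = {}
        for u in sorted(frontier):
            for v in tc.graph.successors(u):
                if v in dist:
                    continue
                if v not in next_candidates or u < next_candidates[v]:
                    next_candidates[v] = u
        d += 1
        frontier = []
        for v, parent in next_candidates.items():
            dist[v] = d
            parents[v] = parent
            frontier.append(v)
    return parents


def shortest_paths(
    tc: EnzymeGraph,
    seed: str,
    all_shortest: bool = False,
) -> list[CandidatePath]:
    """Unit-weight shortest paths from ``seed`` to every reachable node.

    One path per target by default, with the deterministic lexicographic
    predecessor tie-break; ``all_shortest=True`` enumerates every co-shortest
    alternative instead.
    """
    if seed not in tc.graph:
        raise KeyError(f"seed gene {seed!r} not in network")
    if all_shortest:
        import networkx as nx

        out = []
        for target in sorted(tc.graph.nodes):
            if target == seed:
                continue
            try:
                for p in nx.all_shortest_paths(tc.graph, seed, target):
                    out.append(CandidatePath(tuple(p)))
            except nx.NetworkXNoPath:
                continue
        return sorted(out, key=lambda p: (len(p.genes), p.genes))
    parents = _bfs_parents(tc, seed)
    out = []
    for target in sorted(parents):
        chain = [target]
        while chain[-1] != seed:
            chain.append(parents[chain[-1]])
        out.append(CandidatePath(tuple(reversed(chain))))
    return sorted(out, key=lambda p: (len(p.genes), p.genes))


def _live_products(recon: MetabolicReconstruction, reaction: Reaction) -> frozenset[str]:
    # Currency metabolites stay out of live sets except where they are the
    # reaction's primary products (the currency-retention rule).
    return recon.effective_products(reaction)


def check_feasibility(
    path: CandidatePath | tuple[str, ...],
    recon: MetabolicReconstruction,
    enzyme_graph: EnzymeGraph | None = None,
) -> FeasibilityResult:
    """Layered-reachability feasibility check with witness reconstruction.

    At most one intra-gene conversion per gene is considered (a single
    self-linked loop): a second reaction of the gene may consume a first-stage
    product, but chains of intra-gene conversions are not followed.
    """
    if not isinstance(path, CandidatePath):
        path = CandidatePath(tuple(path))
    genes = path.genes
    index = {g: recon.reactions_of(g) for g in genes}
    for g in genes:
        if not index[g]:
            raise ValueError(f"gene {g!r} has no reactions in the reconstruction")
    if enzyme_graph is not None:
        for g1, g2 in path.edges:
            if not enzyme_graph.graph.has_edge(g1, g2):
                raise ValueError(f"path pair {g1}->{g2} is not an enzyme-graph edge")

    # layers[i][metabolite] = back-pointer WitnessStep that put it in the live set
    layers: list[dict[str, WitnessStep]] = []
    first: dict[str, WitnessStep] = {}
    for r in sorted(index[genes[0]], key=lambda r: r.reaction_id):
        for m in sorted(_live_products(recon, r)):
            first.setdefault(m, WitnessStep(genes[0], r.reaction_id, None, m))
    layers.append(first)

    for i, gene in enumerate(genes[1:], start=1):
        prev = layers[-1]
        stage1: dict[str, WitnessStep] = {}
        for r in sorted(index[gene], key=lambda r: r.reaction_id):
            hits = sorted(set(r.substrates) & set(prev))
            if not hits:
                continue
            consumed = hits[0]
            for m in sorted(_live_products(recon, r)):
                stage1.setdefault(m, WitnessStep(gene, r.reaction_id, consumed, m))
        stage2: dict[str, WitnessStep] = {}
        for r in sorted(index[gene], key=lambda r: r.reaction_id):
            hits = sorted(set(r.substrates) & set(stage1))
            if not hits:
                continue
            consumed = hits[0]
            for m in sorted(_live_products(recon, r)):
                if m not in stage1:
                    stage2.setdefault(
                        m, WitnessStep(gene, r.reaction_id, consumed, m, intra_gene=True)
                    )
        live = dict(stage1)
        live.update(stage2)
        if not live:
            return FeasibilityResult(
                feasible=False, path=path, max_feasible_prefix=genes[:i]
            )
        layers.append(live)

    # Reconstruct the witness by walking back-pointers from the smallest final product.
    steps: list[WitnessStep] = []
    target = sorted(layers[-1])[0]
    for i in range(len(genes) - 1, 0, -1):
        step = layers[i][target]
        if step.intra_gene:
            inner = layers[i][step.consumed]
            steps.append(step)
            step = inner
        steps.append(step)
        target = step.consumed
    steps.append(layers[0][target])
    steps.reverse()
    return FeasibilityResult(
        feasible=True,
        path=path,
        feasible_path=FeasiblePath(path=path, witness=tuple(steps)),
        max_feasible_prefix=genes,
    )


def extract_diet_sensitive_paths(
    tc: EnzymeGraph,
    recon: MetabolicReconstruction,
    seeds: SeedSet,
    min_edges: int = 3,
    all_shortest: bool = False,
    keep_prefixes: bool = False,
) -> list[FeasiblePath]:
    """Feasible shortest paths of at least ``min_edges`` edges from each seed.

    ``min_edges=3`` keeps paths longer than two conversions, the default
    working length for biologically interpretable chains.  With
    ``keep_prefixes`` the maximal feasible prefix of each infeasible candidate
    is also returned when long enough.
    """
    seeds = seeds.restricted_to(tc.graph.nodes)
    out: list[FeasiblePath] = []
    seen: set[tuple[str, ...]] = set()
    n_candidates = n_infeasible = 0
    for seed in sorted(seeds.genes):
        for cand in shortest_paths(tc, seed, all_shortest=all_shortest):
            if cand.n_edges < 1:
                continue
            n_candidates += 1
            res = check_feasibility(cand, recon, enzyme_graph=tc)
            if res.feasible:
                if cand.n_edges >= min_edges and cand.genes not in seen:
                    seen.add(cand.genes)
                    out.append(res.feasible_path)
            else:
                n_infeasible += 1
                prefix = res.max_feasible_prefix
                logger.debug("infeasible: %s (feasible prefix %s)", cand.genes, prefix)
                if keep_prefixes and len(prefix) - 1 >= min_edges and prefix not in seen:
                    pref_res = check_feasibility(CandidatePath(prefix), recon, enzyme_graph=tc)
                    if pref_res.feasible:
                        seen.add(prefix)
                        out.append(pref_res.feasible_path)
    logger.info(
        "path extraction: %d seeds, %d candidates, %d infeasible, %d paths kept",
        len(seeds.genes), n_candidates, n_infeasible, len(out),
    )
    return sorted(out, key=lambda p: p.genes)


@dataclass(frozen=True)
class PathForest:
    """Per-seed rooted out-trees formed by the union of unique shortest paths."""

    trees: dict[str, dict[str, str]]  # seed -> {child: parent}

    def nodes_of(self, seed: str) -> set[str]:
        return {seed} | set(self.trees[seed])

    def edges_of(self, seed: str) -> set[tuple[str, str]]:
        return {(parent, child) for child, parent in self.trees[seed].items()}

    @property
    def n_nodes(self) -> int:
        return sum(len(self.nodes_of(s)) for s in self.trees)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.trees.values())


def collapse_to_forest(paths: list[FeasiblePath] | list[CandidatePath]) -> PathForest:
    """Collapse per-seed path unions into rooted out-trees.

    Under the unique tie-broken shortest paths each non-root node has a single
    predecessor, so the union is a tree; contradictory parents raise.
    """
    trees: dict[str, dict[str, str]] = {}
    for p in paths:
        genes = p.genes if not isinstance(p, CandidatePath) else p.genes
        seed = genes[0]
        tree = trees.setdefault(seed, {})
        for parent, child in zip(genes[:-1], genes[1:]):
            if child in tree and tree[child] != parent:
                raise RuntimeError(
                    f"contradictory parents for {child} under seed {seed}: "
                    f"{tree[child]} vs {parent}"
                )
            tree[child] = parent
    return PathForest(trees=trees)


def annotate_paths(
    paths: list[FeasiblePath],
    overlays: dict[str, "object"],
) -> list[dict]:
    """Attach phenotype-association overlays to path nodes.

    ``overlays`` maps an overlay name to a :class:`SimilarityNetwork`; every
    (variable, score, sign) pair involving a path gene is attached to that
    node, and per-path counts by variable are summarized.
    """
    reports = []
    for p in paths:
        node_annotations: dict[str, list[dict]] = {g: [] for g in p.genes}
        counts: dict[str, int] = {}
        for overlay_name, net in sorted(overlays.items()):
            for row in net.pairs.itertuples():
                if row.gene in node_annotations:
                    node_annotations[row.gene].append(
                        {
                            "overlay": overlay_name,
                            "variable": row.variable,
                            "score": float(row.score),
                            "sign": int(row.sign),
                        }
                    )
        for anns in node_annotations.values():
            for a in anns:
                counts[a["variable"]] = 0
        for var in counts:
            counts[var] = sum(
                1 for anns in node_annotations.values() if any(a["variable"] == var for a in anns)
            )
        reports.append(
            {
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
                "annotations": {g: anns for g, anns in node_annotations.items() if anns},
                "summary_counts": dict(sorted(counts.items())),
            }
        )
    return reports
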