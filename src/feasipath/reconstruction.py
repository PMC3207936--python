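"""Metabolic reconstructions and the enzyme-centric graph.

A reconstruction is a list of irreversible (after expansion) reactions, each
catalyzed by a single gene and converting a substrate set into a product set.
The enzyme-centric transform links gene ``g1`` to gene ``g2`` with a directed
edge whenever some reaction of ``g1`` produces a metabolite that some reaction
of ``g2`` consumes.  Ubiquitous currency metabolites (ATP, H2O, NAD...) are
excluded as linking metabolites, because they would connect nearly every pair
of enzymes; the one exception is regions where currency compounds are the
*primary* reactants and products (energy/nucleotide metabolism), which is
operationalized by the retention rule below.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Reaction",
    "MetabolicReconstruction",
    "EnzymeGraph",
    "ReconstructionFormatError",
    "load_reconstruction",
    "load_currency_list",
    "default_currency_list",
    "expand_reversible",
    "build_enzyme_graph",
    "graph_summary",
]

RECON_COLUMNS = ("reaction_id", "genes", "substrates", "products", "reversible")


class ReconstructionFormatError(ValueError):
    """Raised for malformed reaction tables or currency lists."""


@dataclass(frozen=True)
class Reaction:
    """One oriented (or reversible, pre-expansion) enzymatic reaction.

    After loading, multi-gene rows have been split into one reaction per
    catalyzing gene (isoenzyme semantics), so ``genes`` is a singleton for
    every reaction produced by :func:`load_reconstruction`.
    """

    reaction_id: str
    genes: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"reaction {self.reaction_id}: no catalyzing gene")
        if not self.substrates:
            raise ValueError(f"reaction {self.reaction_id}: empty substrate set")
        if not self.products:
            raise ValueError(f"reaction {self.reaction_id}: empty product set")

    @property
    def gene(self) -> str:
        """The catalyzing gene (requires a single-gene reaction)."""
        if len(self.genes) != 1:
            raise ValueError(f"reaction {self.reaction_id} has multiple genes")
        return next(iter(self.genes))


@dataclass(frozen=True)
class MetabolicReconstruction:
    """A set of reactions plus the currency-metabolite list."""

    reactions: tuple[Reaction, ...]
    currency: frozenset[str] = frozenset()

    @property
    def metabolites(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.substrates
            out |= r.products
        return frozenset(out)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def reactions_of(self, gene: str) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if gene in r.genes)

    def effective_products(self, reaction: Reaction) -> frozenset[str]:
        """Products eligible to carry topology: non-currency products, or the
        full product set when currency compounds are the only products
        (currency-as-primary-product retention)."""
        non_currency = reaction.products - self.currency
        return non_currency if non_currency else reaction.products

    def effective_substrates(self, reaction: Reaction) -> frozenset[str]:
        non_currency = reaction.substrates - self.currency
        return non_currency if non_currency else reaction.substrates


def _split_field(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def load_currency_list(path: str | Path) -> frozenset[str]:
    """Read a currency-metabolite list: one identifier per line, ``#`` comments."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return frozenset(out)


def default_currency_list() -> frozenset[str]:
    """The shipped default currency list (Ma & Zeng style conventions)."""
    text = (
        importlib.resources.files("feasipath.data")
        .joinpath("currency_default.txt")
        .read_text(encoding="utf-8")
    )
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return frozenset(out)


def load_reconstruction(
    path: str | Path,
    currency_path: str | Path | None = None,
    currency: Iterable[str] | None = None,
) -> MetabolicReconstruction:
    """Parse a tab-separated reaction table into a reconstruction.

    Expected header: ``reaction_id  genes  substrates  products  reversible``
    with ``;``-separated identifier lists and ``reversible`` in {0, 1}.  Rows
    listing several catalyzing genes are split into one reaction per gene
    (isoenzymes are alternative catalysts, not complexes); split copies get an
    id suffix so reaction ids stay unique.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ReconstructionFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    for col in RECON_COLUMNS:
        if col not in header:
            raise ReconstructionFormatError(f"{path}: missing column {col!r}")
    idx = {col: header.index(col) for col in RECON_COLUMNS}

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) < len(header):
            raise ReconstructionFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        rid = cells[idx["reaction_id"]].strip()
        genes = _split_field(cells[idx["genes"]])
        subs = _split_field(cells[idx["substrates"]])
        prods = _split_field(cells[idx["products"]])
        rev_cell = cells[idx["reversible"]].strip()
        if not rid:
            raise ReconstructionFormatError(f"{path}:{lineno}: empty reaction_id")
        if not genes:
            raise ReconstructionFormatError(f"{path}:{lineno}: empty genes cell")
        if not subs:
            raise ReconstructionFormatError(f"{path}:{lineno}: empty substrates cell")
        if not prods:
            raise ReconstructionFormatError(f"{path}:{lineno}: empty products cell")
        if rev_cell not in {"0", "1"}:
            raise ReconstructionFormatError(
                f"{path}:{lineno}: reversible must be 0 or 1, got {rev_cell!r}"
            )
        if rid in seen_ids:
            raise ReconstructionFormatError(f"{path}:{lineno}: duplicate reaction_id {rid!r}")
        seen_ids.add(rid)
        for gene in sorted(set(genes)):
            sub_id = rid if len(set(genes)) == 1 else f"{rid}__{gene}"
            reactions.append(
                Reaction(
                    reaction_id=sub_id,
                    genes=frozenset({gene}),
                    substrates=frozenset(subs),
                    products=frozenset(prods),
                    reversible=rev_cell == "1",
                )
            )

    cur: frozenset[str] = frozenset()
    if currency_path is not None:
        cur = load_currency_list(currency_path)
    elif currency is not None:
        cur = frozenset(currency)
    return MetabolicReconstruction(reactions=tuple(reactions), currency=cur)


def expand_reversible(recon: MetabolicReconstruction) -> MetabolicReconstruction:
    """Replace each reversible reaction by oriented forward/reverse copies.

    Idempotent: already-irreversible reactions pass through unchanged, so a
    second application is the identity.
    """
    out: list[Reaction] = []
    for r in recon.reactions:
        if not r.reversible:
            out.append(r)
            continue
        out.append(replace(r, reaction_id=f"{r.reaction_id}__fwd", reversible=False))
        out.append(
            Reaction(
                reaction_id=f"{r.reaction_id}__rev",
                genes=r.genes,
                substrates=r.products,
                products=r.substrates,
                reversible=False,
            )
        )
    return MetabolicReconstruction(reactions=tuple(out), currency=recon.currency)


@dataclass
class EnzymeGraph:
    """Directed gene-gene graph from the enzyme-centric transform.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry a sorted tuple
    of linking metabolites under the ``"linking"`` key.  ``reaction_index``
    maps each gene to its reactions; the feasibility checker needs it.
    """

    graph: nx.DiGraph
    reaction_index: Mapping[str, tuple[Reaction, ...]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def linking_metabolites(self, g1: str, g2: str) -> tuple[str, ...]:
        return self.graph.edges[g1, g2]["linking"]

    def subgraph_with_edges(self, edges: Iterable[tuple[str, str]], nodes=None) -> "EnzymeGraph":
        """A new EnzymeGraph restricted to ``edges`` (and optionally ``nodes``)."""
        sub = nx.DiGraph()
        keep_nodes = set(self.graph.nodes) if nodes is None else set(nodes)
        sub.add_nodes_from(n for n in self.graph.nodes if n in keep_nodes)
        for g1, g2 in edges:
            sub.add_edge(g1, g2, **self.graph.edges[g1, g2])
        index = {g: self.reaction_index.get(g, ()) for g in sub.nodes}
        return EnzymeGraph(graph=sub, reaction_index=index)


def _linking_allowed(
    m: str,
    producer: Reaction,
    consumer: Reaction,
    currency: frozenset[str],
    retain_primary_currency: bool,
) -> bool:
    if m not in currency:
        return True
    if not retain_primary_currency:
        return False
    # Currency may link only where it is the primary reactant/product: either
    # the producing reaction makes nothing but currency, or the consuming
    # reaction uses nothing but currency.
    return not (producer.products - currency) or not (consumer.substrates - currency)


def build_enzyme_graph(
    recon: MetabolicReconstruction,
    retain_primary_currency: bool = True,
) -> EnzymeGraph:
    """Enzyme-centric transform of an expanded reconstruction.

    Edge ``g1 -> g2`` exists iff some reaction of ``g1`` produces a metabolite
    consumed by some reaction of ``g2`` (``g1 != g2``) that passes the currency
    rule; the edge is annotated with every such linking metabolite.  Self-edges
    are never stored: intra-gene conversion belongs to the feasibility checker.
    """
    if any(r.reversible for r in recon.reactions):
        raise ValueError("reconstruction must be expanded (no reversible reactions)")
    g = nx.DiGraph()
    index: dict[str, list[Reaction]] = {}
    for r in recon.reactions:
        index.setdefault(r.gene, []).append(r)
    g.add_nodes_from(index)

    producers: dict[str, list[tuple[str, Reaction]]] = {}
    for gene, reactions in index.items():
        for r in reactions:
            for m in r.products:
                producers.setdefault(m, []).append((gene, r))

    linking: dict[tuple[str, str], set[str]] = {}
    for gene2, reactions in index.items():
        for rc in reactions:
            for m in rc.substrates:
                for gene1, rp in producers.get(m, ()):
                    if gene1 == gene2:
                        continue
                    if _linking_allowed(m, rp, rc, recon.currency, retain_primary_currency):
                        linking.setdefault((gene1, gene2), set()).add(m)
    for (g1, g2), mets in sorted(linking.items()):
        g.add_edge(g1, g2, linking=tuple(sorted(mets)))
    return EnzymeGraph(
        graph=g, reaction_index={gene: tuple(rs) for gene, rs in index.items()}
    )


def graph_summary(g: EnzymeGraph) -> dict[str, int]:
    """Node and directed-edge counts (each directed edge counted once)."""
    return {"nodes": g.n_nodes, "edges": g.n_edges}
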