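"""Shortest paths, metabolic feasibility and path forests."""

import networkx as nx
import numpy as np
import pytest

import feasipath as fp
from feasipath.paths import CandidatePath, SeedSet, check_feasibility, shortest_paths
from feasipath.reconstruction import MetabolicReconstruction, Reaction
from oracles import oracle_feasible, random_reconstruction


def _recon(rows, currency=()):
    return MetabolicReconstruction(
        tuple(Reaction(r, frozenset({g}), frozenset(s), frozenset(p)) for r, g, s, p in rows),
        currency=frozenset(currency),
    )


def _chain_graph(*genes):
    recon = _recon(
        [(f"r{i}", g, {f"M{i}"}, {f"M{i + 1}"}) for i, g in enumerate(genes)]
    )
    return recon, fp.build_enzyme_graph(recon)


def test_shortest_paths_chain():
    _, g = _chain_graph("A", "B", "C")
    paths = [p.genes for p in shortest_paths(g, "A")]
    assert paths == [("A", "B"), ("A", "B", "C")]


def test_shortest_paths_diamond_tie_break():
    # A->B->D and A->C->D; the lexicographically smaller predecessor (B) wins
    rows = [
        ("r1", "A", {"M0"}, {"M1", "M2"}),
        ("r2", "B", {"M1"}, {"M3"}),
        ("r3", "C", {"M2"}, {"M4"}),
        ("r4", "D", {"M3", "M4"}, {"M5"}),
    ]
    recon = _recon(rows)
    g = fp.build_enzyme_graph(recon)
    paths = {p.genes[-1]: p.genes for p in shortest_paths(g, "A")}
    assert paths["D"] == ("A", "B", "D")


def test_shortest_paths_match_bfs_distances():
    rng = np.random.default_rng(21)
    for _ in range(100):
        n = int(rng.integers(3, 11))
        g = nx.gnp_random_graph(n, 0.35, directed=True, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        eg = fp.EnzymeGraph(graph=nx.DiGraph(g.edges), reaction_index={})
        eg.graph.add_nodes_from(g.nodes)
        seed = "g0"
        got = {p.genes[-1]: len(p.genes) - 1 for p in shortest_paths(eg, seed)}
        expected = nx.single_source_shortest_path_length(g, seed)
        expected.pop(seed)
        assert got == expected


def test_seed_absent_raises():
    _, g = _chain_graph("A", "B")
    with pytest.raises(KeyError):
        shortest_paths(g, "Q")


def test_fig1_connectivity_without_feasibility(fig1_recon):
    res = check_feasibility(("A", "B", "C", "D"), fig1_recon)
    assert not res.feasible
    assert res.max_feasible_prefix == ("A", "B")


def test_fig1_feasible_with_witness(fig1_recon):
    res = check_feasibility(("Z", "B", "C", "D"), fig1_recon)
    assert res.feasible
    assert res.feasible_path.linking_chain == ("C3", "C4", "C5")


def test_feasibility_rejects_non_edge_pairs(fig1_recon):
    g = fp.build_enzyme_graph(fig1_recon)
    with pytest.raises(ValueError, match="not an enzyme-graph edge"):
        check_feasibility(("A", "C"), fig1_recon, enzyme_graph=g)


def test_single_intra_gene_conversion_allowed():
    # B consumes C2 then converts C3->C4 internally (one self-linked loop)
    rows = [
        ("r1", "A", {"C1"}, {"C2"}),
        ("r2", "B", {"C2"}, {"C3"}),
        ("r3", "B", {"C3"}, {"C4"}),
        ("r4", "C", {"C4"}, {"C5"}),
    ]
    recon = _recon(rows)
    res = check_feasibility(("A", "B", "C"), recon)
    assert res.feasible
    assert any(s.intra_gene for s in res.feasible_path.witness)


def test_intra_gene_chains_are_not_followed():
    # reaching C would need two internal conversions within B: not allowed
    rows = [
        ("r1", "A", {"C1"}, {"C2"}),
        ("r2", "B", {"C2"}, {"C3"}),
        ("r3", "B", {"C3"}, {"C4"}),
        ("r4", "B", {"C4"}, {"C5"}),
        ("r5", "C", {"C5"}, {"C6"}),
    ]
    recon = _recon(rows)
    assert not check_feasibility(("A", "B", "C"), recon).feasible


def _sample_paths(recon, rng, max_len=6, k=5):
    g = fp.build_enzyme_graph(recon)
    out = []
    nodes = g.nodes
    for _ in range(k * 4):
        if len(out) >= k or not nodes:
            break
        start = nodes[int(rng.integers(len(nodes)))]
        path = [start]
        while len(path) < max_len:
            succ = [v for v in sorted(g.graph.successors(path[-1])) if v not in path]
            if not succ or rng.random() < 0.25:
                break
            path.append(succ[int(rng.integers(len(succ)))])
        if len(path) >= 2:
            out.append(tuple(path))
    return out


def test_feasibility_matches_exhaustive_oracle():
    rng = np.random.default_rng(31)
    checked = 0
    while checked < 60:
        recon = random_reconstruction(rng)
        for genes in _sample_paths(recon, rng):
            got = check_feasibility(genes, recon).feasible
            assert got == oracle_feasible(genes, recon), genes
            checked += 1


def test_witness_chain_revalidates_step_by_step():
    """Every witness step must consume what the previous one produced, via a
    real reaction of the right gene (independent re-checker)."""
    rng = np.random.default_rng(32)
    validated = 0
    while validated < 30:
        recon = random_reconstruction(rng)
        for genes in _sample_paths(recon, rng):
            res = check_feasibility(genes, recon)
            if not res.feasible:
                continue
            witness = res.feasible_path.witness
            by_id = {r.reaction_id: r for r in recon.reactions}
            prev_product = None
            for step in witness:
                r = by_id[step.reaction_id]
                assert step.gene in r.genes
                assert step.produced in r.products
                if step.consumed is None:
                    assert step is witness[0]
                else:
                    assert step.consumed in r.substrates
                    assert step.consumed == prev_product
                prev_product = step.produced
            # gene order follows the path, with at most one extra step per gene
            gene_seq = [s.gene for s in witness]
            assert [g for i, g in enumerate(gene_seq) if i == 0 or g != gene_seq[i - 1]] == list(genes)
            validated += 1


def test_pruning_reactions_never_creates_feasibility():
    rng = np.random.default_rng(33)
    tried = 0
    while tried < 25:
        recon = random_reconstruction(rng)
        for genes in _sample_paths(recon, rng):
            if check_feasibility(genes, recon).feasible:
                continue
            keep = [r for r in recon.reactions if rng.random() > 0.3]
            if not set(genes) <= {g for r in keep for g in r.genes}:
                continue
            pruned = MetabolicReconstruction(tuple(keep), recon.currency)
            assert not check_feasibility(genes, pruned).feasible
            tried += 1
            break


def test_extract_fig1_paths(fig1_recon):
    g = fp.build_enzyme_graph(fig1_recon)
    seeds = SeedSet(variable="diet", genes=("A", "Z"))
    found = fp.extract_diet_sensitive_paths(g, fig1_recon, seeds, min_edges=3)
    assert [p.genes for p in found] == [("Z", "B", "C", "D")]


def test_extract_empty_seed_set(fig1_recon):
    g = fp.build_enzyme_graph(fig1_recon)
    found = fp.extract_diet_sensitive_paths(
        g, fig1_recon, SeedSet(variable="diet", genes=()), min_edges=3
    )
    assert found == []


def test_extract_planted_vs_decoys():
    cfg = fp.SimulationConfig(seed=5)
    recon, manifest = fp.simulate_reconstruction(cfg)
    g = fp.build_enzyme_graph(recon)
    seeds = SeedSet(variable="diet", genes=(manifest["chain"][0],))
    found = fp.extract_diet_sensitive_paths(g, recon, seeds, min_edges=3)
    genes_found = {p.genes for p in found}
    assert tuple(manifest["chain"]) in genes_found
    decoy_genes = {x for d in manifest["decoys"] for x in d[1:]}
    assert all(not (set(p) & decoy_genes) for p in genes_found)


def test_forest_collapse_simple():
    paths = [CandidatePath(("A", "B", "C")), CandidatePath(("A", "B", "D"))]
    forest = fp.collapse_to_forest(paths)
    assert forest.trees["A"] == {"B": "A", "C": "B", "D": "B"}
    assert forest.edges_of("A") == {("A", "B"), ("B", "C"), ("B", "D")}


def test_forest_counting_identity():
    rng = np.random.default_rng(34)
    done = 0
    while done < 20:
        recon = random_reconstruction(rng)
        g = fp.build_enzyme_graph(recon)
        roots = [n for n in g.nodes if g.graph.out_degree(n) > 0][:2]
        if not roots:
            continue
        paths = []
        for seed in roots:
            paths.extend(shortest_paths(g, seed))
        if not paths:
            continue
        forest = fp.collapse_to_forest(paths)
        n_nodes = sum(len(forest.nodes_of(s)) for s in forest.trees)
        assert forest.n_edges == n_nodes - len(forest.trees)
        for seed in forest.trees:
            assert seed not in forest.trees[seed]  # root has no parent
        done += 1


def test_annotate_paths_counts(fig1_recon):
    import pandas as pd

    from feasipath.association import SimilarityNetwork

    res = check_feasibility(("Z", "B", "C", "D"), fig1_recon)
    overlay = SimilarityNetwork(
        pairs=pd.DataFrame(
            [("V", "B", 0.9, 1), ("V", "C", -0.8, -1)],
            columns=["variable", "gene", "score", "sign"],
        ),
        threshold=0.7,
        mode="spls",
    )
    reports = fp.annotate_paths([res.feasible_path], {"diet": overlay})
    assert reports[0]["summary_counts"] == {"V": 2}
    assert set(reports[0]["annotations"]) == {"B", "C"}
    empty = fp.annotate_paths([res.feasible_path], {})
    assert empty[0]["annotations"] == {} and empty[0]["summary_counts"] == {}


def test_extraction_is_deterministic(fig1_recon):
    import json

    from feasipath.io import _path_to_dict

    g = fp.build_enzyme_graph(fig1_recon)
    seeds = SeedSet(variable="diet", genes=("A", "Z"))
    a = [_path_to_dict(p) for p in fp.extract_diet_sensitive_paths(g, fig1_recon, seeds, 3)]
    b = [_path_to_dict(p) for p in fp.extract_diet_sensitive_paths(g, fig1_recon, seeds, 3)]
    assert json.dumps(a) == json.dumps(b)
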