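# feasipath

**Diet-sensitive, metabolically feasible path mining in enzyme-centric
metabolic networks.**

`feasipath` is for systems-biology and nutrigenomics researchers who want to
move beyond gene lists: given a genome-scale metabolic reconstruction, a
tissue expression matrix and dietary/plasma phenotype blocks from the same
cohort, it extracts *paths* through the metabolic network that are
(1) anchored at a diet-correlated gene, (2) transcriptionally coexpressed
edge-by-edge, and (3) metabolically feasible — realizable as an unbroken
chain of metabolite conversions, not merely connected in the graph.

## The method

1. **Enzyme-centric graph.** A reaction table (reaction id, catalyzing genes,
   substrates, products, reversibility) is expanded to oriented reactions and
   transformed into a directed gene–gene graph: an edge g₁ → g₂ exists when a
   reaction of g₁ produces a metabolite that a reaction of g₂ consumes.
   Currency metabolites (ATP, H₂O, NAD⁺, ...) are excluded as linking
   metabolites, except where they are a reaction's *primary* reactants or
   products (energy/nucleotide metabolism regions).

2. **AIC coexpression filter.** For each directed edge, the downstream gene's
   expression Y is regressed on the upstream gene's expression X plus
   nuisance factors: Y = β₀ + β₁X + β₂b + β₃s + β₄n + ε, with array batch *b*
   always present and all 8 subsets of {X, s(ex), n(ationality)} enumerated.
   With AIC = 2k − 2 ln L (Gaussian likelihood, k counting mean parameters
   plus the residual variance), the edge survives into the transcriptionally
   coexpressed (TC) network iff X appears in the minimum-AIC model — by
   default with β₁ > 0 (positive coexpression).

3. **Phenotype anchoring.** Diet variables (skew-minimizing log/sqrt/identity
   transform, then standardized) plus dummy-coded covariates are related to
   expression by sparse PLS regression; plasma markers by regularized CCA.
   Pairs whose similarity score — the sum over retained latent dimensions of
   the products of variable–variate correlations — exceeds a threshold
   (0.7 diet, 0.75 plasma by convention) define seed genes and overlays. A
   sample-label permutation test calibrates the null count of passing genes.

4. **Feasible path extraction.** Unit-weight shortest paths (deterministic
   lexicographic tie-break) run from every seed through the TC network; each
   candidate is then checked by layered reachability: the live metabolite set
   after each gene is what its reactions can produce from the previous live
   set, allowing at most one intra-gene conversion per gene (a single
   self-linked loop). Feasible paths carry an explicit witness conversion
   chain and collapse per seed into rooted out-trees. Hypergeometric
   over-representation testing against GMT gene-set collections summarizes
   the selected genes pathway-wise.

## Worked example

The five-gene fixture that motivates the feasibility check
(`examples/01_connectivity_vs_feasibility.py`):

```
enzyme graph: {'nodes': 5, 'edges': 4}
edges: [('A', 'B'), ('B', 'C'), ('C', 'D'), ('Z', 'B')]
A->B->C->D: infeasible (conversion stops after A->B)
Z->B->C->D: FEASIBLE via metabolites C3 -> C4 -> C5
```

A→B→C→D is a connected chain — every consecutive pair shares a metabolite —
but B consumes A's product C2 in a reaction whose product (C7) gene C cannot
use, so no conversion chain runs A→D. From Z, B's other reaction converts
C3→C4 and the chain C3→C4→C5(→C6) closes end to end.

The full pipeline on a synthetic 19-sample cohort with a planted feasible
chain and three connectivity-only decoys (`examples/04_full_pipeline.py`):

```
planted chain: ['PG1', 'PG2', 'PG3', 'PG4', 'PG5']
extracted paths: [['PG1', 'PG2', 'PG3', 'PG4'], ['PG1', 'PG2', 'PG3', 'PG4', 'PG5']]
decoy genes in any extracted path: False
```

The planted path (and its feasible sub-path from a secondary seed) is
recovered; the decoys — reachable in the graph but not realizable as
metabolite conversion — are rejected. `examples/02_aic_coexpression.py` and
`examples/03_diet_association.py` show the coexpression filter and the
diet-association layer in isolation, including a permutation null with
median 0 passing genes on label-shuffled data.

## Command line

Every stage is also a CLI subcommand over the same library code:

```sh
feasipath simulate --seed 8 --out data/
feasipath build-graph data/reconstruction.tsv --out out/graph
feasipath tc-network data/reconstruction.tsv --expression data/expression.tsv \
    --covariates data/covariates.tsv --out out/tc
feasipath associate --phenotypes data/phenotypes.tsv --expression data/expression.tsv \
    --covariates data/covariates.tsv --dimensions 3 --keep-x 2 -R 100 --out out/pairs.tsv
feasipath paths data/reconstruction.tsv --tc-network out/tc.graphml \
    --seeds out/pairs.tsv --out out/paths.json
feasipath run --config run.json --seed 8
```

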