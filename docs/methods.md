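# Methods

This note documents the models and procedures implemented in `feasipath`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Enzyme-centric graph construction

A reconstruction is a list of reactions, each carrying one catalyzing gene
(rows listing several genes are split into one reaction per gene: isoenzyme
lists are treated as alternative catalysts, not complexes — reconstructions
that encode complexes should pre-join them into a single identifier).
Reversible reactions are expanded into forward/reverse copies before any
analysis, fixing an orientation per copy; the feasibility checker therefore
sees only oriented reactions.

The directed edge g₁ → g₂ is created when some reaction of g₁ produces a
metabolite that some reaction of g₂ consumes. Metabolite identifiers are
opaque strings; if inputs encode compartments, identical strings match and no
de-compartmentalization is attempted.

**Currency handling.** Ubiquitous cofactors link nearly every enzyme pair and
are excluded as linking metabolites. A default list ships with the package
(H₂O, H⁺, ATP/ADP/AMP, O₂, CO₂, Pi, PPi, NAD(H), NADP(H), CoA); users supply
their own list in their reconstruction's namespace. The exception is the
*retention rule*: a currency metabolite may link two reactions when excluding
currency would leave the producing reaction with no products or the consuming
reaction with no substrates — i.e. where currency compounds are the primary
reactants and products, as in adenylate/nucleotide metabolism. The rule is a
per-reaction-pair test and can be disabled.

Self-edges are never stored at the graph level; conversion within one gene is
the feasibility checker's concern.

## AIC coexpression filtering

For each directed edge, downstream expression is modeled as

Y = β₀ + β₁·X + β₂·b + β₃·s + β₄·n + ε

with X the upstream gene's expression and b/s/n categorical batch, sex and
nationality (treatment contrasts, reference = lexicographically first level;
single-level factors contribute no columns). Batch is included in every
model as a platform-wide technical effect; the 8 candidate models are the
subsets of {X, s, n}. Each candidate is an OLS fit scored by
AIC = 2k − 2 ln L, with the Gaussian profile likelihood
ln L = −n/2·(ln 2πσ̂² + 1), σ̂² = RSS/n, and k = (mean parameters) + 1 for
the residual variance. Numerical choices:

- a perfect fit (σ̂² = 0) is floored at 1e−12 × var(Y) with a logged warning,
  so degenerate synthetic inputs rank first rather than crash;
- exact AIC ties prefer fewer parameters, then the model *without* X
  (conservative coexpression calls), then a fixed subset order;
- rank-deficient designs (e.g. a factor confounded with batch) raise an
  error naming the columns rather than silently dropping terms.

The edge survives iff X is in the minimum-AIC model and (by default) β₁ > 0;
`allow_negative=True` restores the presence-only rule. Both behaviors exist
because "present in the optimal model" and "positive coexpression" are both
defensible readings; positive-only is the default since metabolic
hand-off between consecutive enzymes is the signal of interest. Under
independence the presence-only rule admits an edge with asymptotic
probability P(χ²₁ > 2) ≈ 15.7%, the signed rule ≈ 7.9%; the test suite
verifies both at n = 200.

A variance filter (default: drop the lowest 10% of genes by sample variance,
ties broken by gene id) mirrors standard expression pre-filtering.

## Phenotype association

Diet/plasma variables are first transformed by whichever of identity, sqrt
(non-negative columns) or log (strictly positive columns) minimizes absolute
sample skewness, then standardized; choices are recorded per variable.
Dummy-coded sex/nationality/batch columns are appended to the predictor block
and standardized like the rest, so covariate-driven expression structure is
absorbed by the decomposition rather than masquerading as diet signal.

**Sparse PLS (regression mode).** Per dimension, the dominant singular pair
of the current cross-covariance is obtained by alternating power iterations;
after each update all but the keepX (keepY) largest-magnitude weight entries
are zeroed and the survivors soft-thresholded by the largest excluded
magnitude. Both blocks are deflated by regression on the X-variate. With
full keeps the algorithm is exactly dense PLS (verified against an
independent NIPALS implementation to 1e−8). Default keepY = all (genes are
selected by the similarity threshold, not by weight sparsity); the pipeline
default keepX = 2 per dimension reflects the expectation that one or two
diet variables drive any given latent dimension.

**Dimension choice.** Q²ₕ = 1 − PRESSₕ/RSSₕ₋₁ is computed by k-fold
cross-validation; dimensions are retained while Q²ₕ ≥ 0.0975 (the Tenenhaus
convention) with a floor of one dimension. The pipeline default, however,
fixes H = 3: on expression blocks that are mostly noise genes the aggregate
Q² is dominated by the unpredictable majority and understates dimensions
that carry real but narrow diet signal; fixing a small H after inspection is
the same pragmatic choice made in the multivariate-nutrigenomics literature
this package serves. Q²-based selection remains available
(`n_components=None`).

**Regularized CCA.** Canonical weights solve the whitened cross-covariance
SVD built from (Sxx + λ₁I) and (Syy + λ₂I); λ = 0 with p > n raises with
advice to regularize. Canonical correlations are non-increasing and clipped
to [0, 1]. As λ → ∞ the weights converge to the singular vectors of the
cross-covariance (verified to 1e−6 at λ = 1e6). λ is chosen on a grid by
cross-validated held-out first canonical correlation, ties toward smaller λ.

**Similarity network.** score(i, j) = Σₕ corr(xᵢ, zₕ)·corr(yⱼ, zₕ) over the
retained dimensions, where zₕ is the X-variate (sPLS) or the averaged
X/Y-variate (rCCA). Correlations are computed against a QR-orthonormalized
basis of the variates; with an orthonormal basis, Bessel's inequality plus
Cauchy–Schwarz guarantee |score| ≤ 1. Pairs with |score| above the threshold
(default 0.7) are retained with their sign. Thresholding is monotone: a
higher threshold always yields a subset.

**Permutation null.** The X block's sample labels are permuted R times
(default 100), the sPLS + similarity pipeline re-run, and the count of genes
passing the threshold for the focal variable recorded; mean and median are
reported. Replicate generators derive from a single seed by counter offset,
so the procedure is bit-reproducible.

## Feasible path extraction

Shortest paths (unit weights, directionality respected) run from each seed
gene to every reachable node of the TC network. One path per target is kept,
with a deterministic tie-break — the parent of every node in the BFS tree is
its lexicographically smallest shortest-distance predecessor — which makes
per-seed path unions collapse into rooted out-trees by construction.
`all_shortest=True` enumerates co-shortest alternatives instead, relaxing
the forest guarantee to a DAG.

Feasibility is decided by layered reachability. The initial live set is the
seed's currency-filtered products (the seed must start the conversion chain,
being the diet-correlated upstream end). At each subsequent gene the live
set becomes the products of its reactions that consume a live metabolite,
optionally extended by ONE intra-gene conversion: a second reaction of the
same gene consuming a first-stage product. Chains of intra-gene conversions
are deliberately not followed — a single self-linked loop per gene is the
modeling boundary. Currency metabolites stay out of live sets except where
the retention rule admits them. The path is feasible iff the live set is
non-empty after the last gene; back-pointers reconstruct a witness chain of
(gene, reaction, consumed, produced) steps, and an infeasible path reports
its maximal feasible prefix (returned only under `keep_prefixes`).

Paths shorter than `min_edges` (default 3 edges, i.e. "longer than two
conversions") are discarded; the node-count reading of path length is
available by setting `min_edges=2`. Results are deduplicated by gene
sequence and fully deterministic.

## Enrichment

Upper-tail hypergeometric tests (P(Obs ≥ observed)) score a selected gene
list against GMT gene-set collections; the universe is the intersection of
the analysis gene space with the collection, out-of-universe members being
dropped with a log line. Expected count = set_size·|selected|/|universe|.
Raw p-values are reported by default; Benjamini–Hochberg adjustment is a
flag. Community detection on the TC network is out of scope; an igraph-based
workflow can consume the exported GraphML directly.

## Synthetic data

The generator emulates the study design the method assumes, at the scale of
a small multicentre cohort: 19 samples, two array batches, two sexes, two
nationalities, additive per-gene covariate shifts (defaults 0.5/0.3/0.3 sd),
planted linear coexpression along a 5-gene chain (slope 1.0, noise sd 0.3),
three connectivity-only decoy paths sharing the chain's seed gene (each
decoy gene consumes the incoming metabolite but produces only a dead-end
compound), currency cofactors sprinkled into reactions, and a focal diet
variable whose correlation with the seed gene's expression is 0.95, plus
independent and log-normal filler variables. Planted downstream genes
receive their own covariate shifts rather than accumulating their
ancestors' — coexpression acts on the covariate-adjusted signal, which is
the structure the edge-wise model estimates. Every planted object is
re-validated (feasibility, decoy infeasibility) before a dataset is handed
out, and all outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: realistic genome-scale topology
(thousand-enzyme reconstructions with hub structure and redundancy),
probe-level microarray artifacts,
heavy-tailed expression noise, correlated diet variables, or missing data.
Passing tests therefore demonstrate correctness of the algorithms and their
calibration under the stated model, not robustness to those real-data
features.

## Problem sizes used in validation

Oracle-equivalence checks run on 200 random reconstructions/paths (≤ 12
genes, ≤ 30 reactions, ≤ 6-gene paths) against exhaustive enumeration; the
AIC null calibration uses 2000 replicates at n = 200; end-to-end planted-path
recovery uses 100 replicates of the default 19-sample configuration; the
permutation null uses 100 permutations over 50 genes. These sizes make every
check exact or tightly calibrated while keeping the full validation suite
fast enough to run routinely.

## Known limitations

- Feasibility is qualitative reachability: stoichiometry, mass balance and
  flux are out of scope (a flux-balance layer would need a different input
  format and solver).
- The single intra-gene loop allowance is a hard boundary; pathways that
  require two internal conversions within one enzyme's reaction set are
  reported infeasible.
- The similarity score is a rank-H bilinear approximation; with small
  retained H it understates strong marginal correlations that span multiple
  dimensions.
- With 19 samples the AIC filter's null inclusion rate is somewhat above its
  asymptotic value; edge calls at this scale are screening, not inference.
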