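"""Synthetic reconstructions, expression matrices and phenotype blocks.

The generator emulates the structure the pipeline assumes so every module is
testable offline: a small cohort (19 samples, two batches, two sexes, two
nationalities, mirroring the kind of multicentre nutrigenomics study the
method targets), planted linear gene-gene coexpression with additive covariate
shifts and Gaussian noise, a dietary focal variable covarying with seed-gene
expression, and reconstructions wired to contain one metabolically feasible
chain plus connectivity-only decoy paths (edges that share metabolites without
an unbroken conversion chain).

Everything is deterministic given ``SimulationConfig.seed``; each operation
derives its stream from the seed plus a fixed stage tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import SampleCovariates
from .paths import CandidatePath, check_feasibility
from .reconstruction import EnzymeGraph, MetabolicReconstruction, Reaction

__all__ = [
    "SimulationConfig",
    "make_fig1_reconstruction",
    "FIG1_CONNECTED_INFEASIBLE",
    "FIG1_FEASIBLE",
    "simulate_reconstruction",
    "simulate_expression",
    "simulate_phenotypes",
]

_STAGE = {"reconstruction": 1, "expression": 2, "phenotypes": 3}

# The worked example: genes A and D are linked through B and C by shared
# metabolites, yet no conversion chain runs A->D, while Z->B->C->D converts
# C3 -> C4 -> C5 (-> C6).
FIG1_CONNECTED_INFEASIBLE = ("A", "B", "C", "D")
FIG1_FEASIBLE = ("Z", "B", "C", "D")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults mimic the target cohort scale."""

    seed: int = 0
    # cohort
    n_samples: int = 19
    n_batches: int = 2
    n_sexes: int = 2
    n_nationalities: int = 2
    batch_effect: float = 0.5  # additive shift per level, in sd units
    sex_effect: float = 0.3
    nationality_effect: float = 0.3
    # coexpression
    planted_slope: float = 1.0
    noise_sd: float = 0.3
    # reconstruction shape
    chain_length: int = 5  # genes in the planted feasible chain
    decoy_length: int = 4  # genes per connectivity-only decoy path
    n_decoys: int = 3
    n_filler_genes: int = 6
    reactions_per_filler: int = 2
    metabolite_pool: int = 30
    currency_fraction: float = 0.15  # chance of sprinkling a currency cofactor
    # phenotypes
    diet_strength: float = 0.95  # target correlation of the focal diet variable
    n_filler_variables: int = 4
    n_skewed_variables: int = 2
    focal_variable: str = "pufa_intake"

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.chain_length < 2 or self.decoy_length < 3:
            raise ValueError("infeasible simulation shape parameters")
        if self.chain_length > self.n_samples + self.n_filler_genes + 50:
            raise ValueError("chain longer than plausible gene count")
        if not 0 <= self.diet_strength <= 1:
            raise ValueError("diet_strength must be in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), _STAGE[stage]])
        )

    @property
    def chain_genes(self) -> tuple[str, ...]:
        return tuple(f"PG{i}" for i in range(1, self.chain_length + 1))

    @property
    def chain_edges(self) -> tuple[tuple[str, str], ...]:
        g = self.chain_genes
        return tuple(zip(g[:-1], g[1:]))


def make_fig1_reconstruction() -> MetabolicReconstruction:
    """Fixed five-gene fixture separating connectivity from feasibility."""
    rows = [
        ("rA", "A", {"C1"}, {"C2"}),
        ("rB1", "B", {"C2"}, {"C7"}),
        ("rB2", "B", {"C3"}, {"C4"}),
        ("rZ", "Z", {"C0"}, {"C3"}),
        ("rC", "C", {"C4"}, {"C5"}),
        ("rD", "D", {"C5"}, {"C6"}),
    ]
    reactions = tuple(
        Reaction(rid, frozenset({g}), frozenset(s), frozenset(p)) for rid, g, s, p in rows
    )
    return MetabolicReconstruction(reactions=reactions, currency=frozenset())


_CURRENCY = ("ATP", "ADP", "H2O", "NAD+", "NADH", "Pi")


def simulate_reconstruction(
    cfg: SimulationConfig,
) -> tuple[MetabolicReconstruction, dict]:
    """Random reconstruction with one planted feasible chain and decoy paths.

    The manifest lists the planted chain and the decoy gene paths; each decoy
    shares the chain's seed gene and is connected edge-by-edge, but the gene
    that consumes the incoming metabolite produces only a dead-end compound,
    so no conversion chain exists beyond the first pair.  The manifest is
    re-validated with the feasibility checker before returning.
    """
    rng = cfg.rng("reconstruction")
    reactions: list[Reaction] = []

    def rx(rid, gene, subs, prods):
        reactions.append(
            Reaction(rid, frozenset({gene}), frozenset(subs), frozenset(prods))
        )

    chain = list(cfg.chain_genes)
    for i, gene in enumerate(chain, start=1):
        subs, prods = {f"CM{i}"}, {f"CM{i + 1}"}
        if rng.random() < cfg.currency_fraction:
            subs = subs | {str(rng.choice(_CURRENCY))}
        if rng.random() < cfg.currency_fraction:
            prods = prods | {str(rng.choice(_CURRENCY))}
        rx(f"rp{i}", gene, subs, prods)

    decoys: list[list[str]] = []
    for d in range(cfg.n_decoys):
        genes = [chain[0]] + [f"DG{d}_{j}" for j in range(2, cfg.decoy_length + 1)]
        # first decoy gene consumes the seed's product but makes a dead end
        rx(f"rd{d}_2a", genes[1], {"CM2"}, {f"DEAD{d}_2"})
        rx(f"rd{d}_2b", genes[1], {f"Q{d}_2"}, {f"R{d}_2"})
        for j in range(3, cfg.decoy_length):
            rx(f"rd{d}_{j}a", genes[j - 1], {f"R{d}_{j - 1}"}, {f"DEAD{d}_{j}"})
            rx(f"rd{d}_{j}b", genes[j - 1], {f"Q{d}_{j}"}, {f"R{d}_{j}"})
        rx(
            f"rd{d}_{cfg.decoy_length}a",
            genes[-1],
            {f"R{d}_{cfg.decoy_length - 1}"},
            {f"DEAD{d}_{cfg.decoy_length}"},
        )
        decoys.append(genes)

    pool = [f"FM{k}" for k in range(cfg.metabolite_pool)]
    for f in range(cfg.n_filler_genes):
        gene = f"FG{f}"
        for r in range(cfg.reactions_per_filler):
            subs = {str(m) for m in rng.choice(pool, size=1)}
            prods = {str(m) for m in rng.choice(pool, size=1)}
            if prods == subs:
                prods = {f"FM{(int(next(iter(subs))[2:]) + 1) % cfg.metabolite_pool}"}
            if rng.random() < cfg.currency_fraction:
                subs |= {str(rng.choice(_CURRENCY))}
            if rng.random() < cfg.currency_fraction:
                prods |= {str(rng.choice(_CURRENCY))}
            rx(f"rf{f}_{r}", gene, subs, prods)

    recon = MetabolicReconstruction(
        reactions=tuple(reactions), currency=frozenset(_CURRENCY)
    )
    manifest = {"chain": chain, "decoys": decoys}

    # manifest soundness: planted objects must validate before being handed out
    assert check_feasibility(CandidatePath(tuple(chain)), recon).feasible
    for decoy in decoys:
        assert not check_feasibility(CandidatePath(tuple(decoy)), recon).feasible
    return recon, manifest


def _covariates(cfg: SimulationConfig, rng: np.random.Generator) -> SampleCovariates:
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]

    def levels(prefix: str, k: int) -> list[str]:
        base = [f"{prefix}{j + 1}" for j in range(k)]
        assigned = [base[i % k] for i in range(cfg.n_samples)]
        rng.shuffle(assigned)
        return assigned

    table = pd.DataFrame(
        {
            "batch": levels("b", cfg.n_batches),
            "sex": levels("sex", cfg.n_sexes),
            "nationality": levels("nat", cfg.n_nationalities),
        },
        index=samples,
    )
    return SampleCovariates(table)


def simulate_expression(
    graph: EnzymeGraph,
    cfg: SimulationConfig,
    planted: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, SampleCovariates]:
    """Expression for every graph gene, with planted linear edge effects.

    Upstream genes are standard normals plus per-gene covariate shifts; a
    planted downstream gene is ``slope * upstream_signal + shifts + noise``,
    where ``upstream_signal`` is the upstream profile minus its own covariate
    shifts — each gene carries its own batch/sex/nationality offsets rather
    than accumulating its ancestors'.  Non-planted genes are independent.
    Planted edges must form a DAG.
    """
    if planted is None:
        planted = {e: cfg.planted_slope for e in cfg.chain_edges if graph.graph.has_edge(*e)}
    for u, v in planted:
        if not graph.graph.has_edge(u, v):
            raise ValueError(f"planted edge {u}->{v} not in graph")
    rng = cfg.rng("expression")
    cov = _covariates(cfg, rng)
    genes = sorted(graph.graph.nodes)
    n = cfg.n_samples

    shifts = {}
    for gene in genes:
        shift = np.zeros(n)
        for factor, effect in (
            ("batch", cfg.batch_effect),
            ("sex", cfg.sex_effect),
            ("nationality", cfg.nationality_effect),
        ):
            level_effects = {
                lv: rng.normal(0, effect) for lv in sorted(cov.table[factor].unique())
            }
            shift += np.array([level_effects[lv] for lv in cov.table[factor]])
        shifts[gene] = shift

    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for (u, v), slope in sorted(planted.items()):
        parents[v].append((u, slope))

    expr: dict[str, np.ndarray] = {}
    remaining = list(genes)
    guard = 0
    while remaining:
        progressed = False
        for gene in list(remaining):
            if all(u in expr for u, _ in parents[gene]):
                base = sum(
                    (slope * (expr[u] - shifts[u]) for u, slope in parents[gene]),
                    np.zeros(n),
                )
                noise_sd = cfg.noise_sd if parents[gene] else 1.0
                expr[gene] = base + shifts[gene] + rng.normal(0, noise_sd, n)
                remaining.remove(gene)
                progressed = True
        guard += 1
        if not progressed or guard > len(genes) + 2:
            raise ValueError("planted edges contain a cycle")
    mat = pd.DataFrame(
        {s: [expr[g][i] for g in genes] for i, s in enumerate(cov.samples)}, index=genes
    )
    return mat, cov


def simulate_phenotypes(
    expr: pd.DataFrame,
    seed_genes,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Raw (untransformed) phenotype block with a planted diet-gene covariance.

    The focal variable is the standardized mean of the seed genes mixed with
    noise so its correlation with that signal is ``diet_strength``; filler
    variables are independent normals and skewed fillers are log-normal, there
    to exercise the transform chooser.
    """
    seed_genes = [g for g in seed_genes]
    missing = [g for g in seed_genes if g not in expr.index]
    if missing:
        raise ValueError(f"seed genes absent from expression: {missing}")
    rng = cfg.rng("phenotypes")
    n = expr.shape[1]
    cols: dict[str, np.ndarray] = {}
    if seed_genes and cfg.diet_strength > 0:
        signal = expr.loc[seed_genes].mean(axis=0).to_numpy()
        signal = (signal - signal.mean()) / signal.std(ddof=1)
        rho = cfg.diet_strength
        cols[cfg.focal_variable] = rho * signal + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
    else:
        cols[cfg.focal_variable] = rng.normal(0, 1, n)
    for i in range(cfg.n_filler_variables):
        cols[f"diet_var{i + 1}"] = rng.normal(0, 1, n)
    for i in range(cfg.n_skewed_variables):
        cols[f"diet_skewed{i + 1}"] = np.exp(rng.normal(0, 1, n))
    return pd.DataFrame(cols, index=list(expr.columns))
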