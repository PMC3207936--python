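"""AIC model selection for edge-wise transcriptional coexpression.

Each directed enzyme-graph edge ``g1 -> g2`` is tested by regressing gene-2
expression on gene-1 expression plus nuisance factors.  Array batch ``b`` is
always in the design (a platform-wide technical effect); the eight candidate
models are the subsets of {X, s, n} (upstream expression, sex, nationality)
added on top of it.  The pair is called coexpressed when X appears in the
minimum-AIC model, with AIC = 2k - 2 ln L under a Gaussian likelihood where k
counts the mean parameters plus one for the residual variance.  By default the
call additionally requires a positive slope on X (positive coexpression);
``allow_negative=True`` restores the presence-only rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .reconstruction import EnzymeGraph

__all__ = [
    "SampleCovariates",
    "CandidateModel",
    "CoexpressionResult",
    "FitError",
    "variance_filter",
    "fit_candidate_model",
    "select_optimal_model",
    "build_tc_network",
    "ALL_SUBSETS",
]

logger = logging.getLogger(__name__)

# Fixed enumeration order of the candidate predictor subsets (b always present).
ALL_SUBSETS: tuple[frozenset[str], ...] = tuple(
    frozenset(c) for r in range(4) for c in combinations(("X", "s", "n"), r)
)

# Relative floor applied to a zero ML residual variance so that perfect fits
# (degenerate synthetic inputs) yield a finite, strongly favourable lnL.
_VARIANCE_FLOOR_FRACTION = 1e-12


class FitError(ValueError):
    """Raised for rank-deficient designs or missing genes."""


@dataclass(frozen=True)
class SampleCovariates:
    """Per-sample batch/sex/nationality factors, aligned to expression columns."""

    table: pd.DataFrame  # index = sample ids; columns include batch, sex, nationality

    def __post_init__(self) -> None:
        missing = {"batch", "sex", "nationality"} - set(self.table.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def aligned(self, samples) -> "SampleCovariates":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValueError(f"samples missing from covariates: {missing[:5]}")
        return SampleCovariates(self.table.loc[list(samples)])


@dataclass(frozen=True)
class CandidateModel:
    """One OLS fit of downstream expression on a predictor subset."""

    subset: frozenset[str]
    columns: tuple[str, ...]
    coefficients: tuple[float, ...]
    residual_variance: float  # ML estimate (RSS / n), floored if degenerate
    k: int  # mean parameters + 1 for the residual variance
    lnL: float
    aic: float

    @property
    def includes_x(self) -> bool:
        return "X" in self.subset

    @property
    def beta_x(self) -> float | None:
        if "X" not in self.subset:
            return None
        return self.coefficients[self.columns.index("X")]


@dataclass(frozen=True)
class CoexpressionResult:
    gene1: str
    gene2: str
    optimal: CandidateModel
    candidates: tuple[CandidateModel, ...]

    @property
    def includes_x(self) -> bool:
        return self.optimal.includes_x

    @property
    def beta_x(self) -> float | None:
        return self.optimal.beta_x


def variance_filter(expr: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Drop the ``floor(fraction * G)`` genes with the smallest sample variance.

    Mirrors the usual pre-filter that discards the flattest expression
    profiles before network testing.  Ties break by gene id order.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n_drop = math.floor(fraction * expr.shape[0])
    if n_drop == 0:
        return expr.copy()
    variances = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (variances[g], g))
    dropped = set(order[:n_drop])
    logger.info("variance filter: dropping %d of %d genes", n_drop, expr.shape[0])
    return expr.loc[[g for g in expr.index if g not in dropped]]


def _factor_columns(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    # Treatment contrasts, reference = lexicographically first level.
    levels = sorted(map(str, values.unique()))
    cols, names = [], []
    str_vals = values.astype(str).to_numpy()
    for level in levels[1:]:
        cols.append((str_vals == level).astype(float))
        names.append(f"{name}[{level}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def build_design(
    x: np.ndarray | None,
    cov: SampleCovariates,
    subset: frozenset[str],
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + batch contrasts + requested subset columns."""
    n = len(cov.table)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    bmat, bnames = _factor_columns(cov.table["batch"], "batch")
    blocks.append(bmat)
    names += bnames
    if "X" in subset:
        if x is None:
            raise FitError("subset requests X but no upstream expression given")
        blocks.append(np.asarray(x, dtype=float).reshape(-1, 1))
        names.append("X")
    if "s" in subset:
        smat, snames = _factor_columns(cov.table["sex"], "sex")
        blocks.append(smat)
        names += snames
    if "n" in subset:
        nmat, nnames = _factor_columns(cov.table["nationality"], "nationality")
        blocks.append(nmat)
        names += nnames
    return np.column_stack([b for b in blocks if b.size or b.shape[1] == 0]), names


def fit_candidate_model(
    y: np.ndarray,
    x: np.ndarray | None,
    cov: SampleCovariates,
    subset: frozenset[str],
) -> CandidateModel:
    """OLS fit with Gaussian profile log-likelihood and AIC = 2k - 2 lnL."""
    y = np.asarray(y, dtype=float)
    design, names = build_design(x, cov, subset)
    n, p = design.shape
    if n < p + 1:
        raise FitError(f"too few samples ({n}) for {p} parameters")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise FitError(f"rank-deficient design (rank {rank} < {p} columns): {names}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sigma2 = float(resid @ resid) / n
    y_var = float(np.var(y))
    floor = _VARIANCE_FLOOR_FRACTION * (y_var if y_var > 0 else 1.0)
    if sigma2 < floor:
        logger.warning("near-perfect fit (residual variance %.3g floored)", sigma2)
        sigma2 = floor
    lnL = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = p + 1
    aic = 2 * k - 2 * lnL
    return CandidateModel(
        subset=subset,
        columns=tuple(names),
        coefficients=tuple(float(b) for b in beta),
        residual_variance=sigma2,
        k=k,
        lnL=lnL,
        aic=aic,
    )


def _tie_key(m: CandidateModel) -> tuple:
    # Exact AIC ties: prefer fewer parameters, then the model without X
    # (conservative coexpression calls), then a fixed name order.
    return (m.aic, m.k, m.includes_x, tuple(sorted(m.subset)))


def select_optimal_model(
    gene2: str,
    gene1: str,
    expr: pd.DataFrame,
    cov: SampleCovariates,
) -> CoexpressionResult:
    """Enumerate all 8 candidate models for the pair and return the AIC winner."""
    for g in (gene1, gene2):
        if g not in expr.index:
            raise FitError(f"gene {g!r} absent from expression matrix")
    cov = cov.aligned(expr.columns)
    y = expr.loc[gene2].to_numpy(dtype=float)
    x = expr.loc[gene1].to_numpy(dtype=float)
    candidates = tuple(
        fit_candidate_model(y, x if "X" in s else None, cov, s) for s in ALL_SUBSETS
    )
    optimal = min(candidates, key=_tie_key)
    return CoexpressionResult(gene1=gene1, gene2=gene2, optimal=optimal, candidates=candidates)


def build_tc_network(
    g: EnzymeGraph,
    expr: pd.DataFrame,
    cov: SampleCovariates,
    allow_negative: bool = False,
) -> EnzymeGraph:
    """Transcriptionally coexpressed (TC) subnetwork of an enzyme graph.

    Nodes without an expression row are dropped; a surviving directed edge is
    kept iff the AIC winner for its pair contains upstream expression, and
    (unless ``allow_negative``) with a positive slope.
    """
    if allow_negative:
        logger.warning("TC network: negative-slope coexpression calls enabled")
    else:
        logger.info("TC network: requiring positive coexpression (beta_X > 0)")
    measured = [n for n in g.graph.nodes if n in expr.index]
    kept_edges = []
    for g1, g2 in sorted(g.graph.edges):
        if g1 not in expr.index or g2 not in expr.index:
            continue
        res = select_optimal_model(g2, g1, expr, cov)
        if not res.includes_x:
            continue
        if not allow_negative and (res.beta_x is None or res.beta_x <= 0):
            continue
        kept_edges.append((g1, g2))
    logger.info(
        "TC network: %d/%d nodes measured, %d/%d edges kept",
        len(measured), g.n_nodes, len(kept_edges), g.n_edges,
    )
    return g.subgraph_with_edges(kept_edges, nodes=measured)
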