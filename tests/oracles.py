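"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from scratch against the definitions
(brute-force enumeration, closed forms, a separate NIPALS implementation,
statsmodels fits) and never calls the code paths it validates.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from feasipath.reconstruction import (
    MetabolicReconstruction,
    Reaction,
    expand_reversible,
)


# --- enzyme graph ----------------------------------------------------------

def brute_force_enzyme_edges(
    recon: MetabolicReconstruction, retain_primary_currency: bool = True
) -> dict[tuple[str, str], set[str]]:
    """Triple loop over (gene1, gene2, metabolite) with the currency rule."""
    edges: dict[tuple[str, str], set[str]] = {}
    genes = sorted(recon.genes)
    for g1 in genes:
        for g2 in genes:
            if g1 == g2:
                continue
            for rp in recon.reactions_of(g1):
                for rc in recon.reactions_of(g2):
                    for m in rp.products:
                        if m not in rc.substrates:
                            continue
                        if m in recon.currency:
                            if not retain_primary_currency:
                                continue
                            if (rp.products - recon.currency) and (
                                rc.substrates - recon.currency
                            ):
                                continue
                        edges.setdefault((g1, g2), set()).add(m)
    return edges


def random_reconstruction(
    rng: np.random.Generator,
    max_genes: int = 12,
    max_reactions: int = 30,
) -> MetabolicReconstruction:
    n_genes = int(rng.integers(2, max_genes + 1))
    n_reactions = int(rng.integers(n_genes, max_reactions + 1))
    mets = [f"M{i}" for i in range(int(rng.integers(4, 12)))]
    currency = ["CUR1", "CUR2"]
    pool = mets + currency
    reactions = []
    for i in range(n_reactions):
        gene = f"G{int(rng.integers(n_genes))}"
        subs = set(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
        prods = set(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
        reactions.append(
            Reaction(
                f"r{i}",
                frozenset({gene}),
                frozenset(map(str, subs)),
                frozenset(map(str, prods)),
                reversible=bool(rng.random() < 0.2),
            )
        )
    return expand_reversible(
        MetabolicReconstruction(tuple(reactions), frozenset(currency))
    )


# --- feasibility -----------------------------------------------------------

def _effective_products(recon: MetabolicReconstruction, r: Reaction) -> frozenset[str]:
    non = r.products - recon.currency
    return non if non else r.products


def oracle_feasible(genes: tuple[str, ...], recon: MetabolicReconstruction) -> bool:
    """Exhaustive enumeration of all reaction-step conversion chains, allowing
    at most one intra-gene conversion per gene."""

    def step(i: int, m: str) -> bool:
        if i == len(genes):
            return True
        for r in recon.reactions_of(genes[i]):
            if m not in r.substrates:
                continue
            for m2 in _effective_products(recon, r):
                if step(i + 1, m2):
                    return True
            for mid in _effective_products(recon, r):
                for r2 in recon.reactions_of(genes[i]):
                    if mid in r2.substrates:
                        for m3 in _effective_products(recon, r2):
                            if step(i + 1, m3):
                                return True
        return False

    for r0 in recon.reactions_of(genes[0]):
        for m0 in _effective_products(recon, r0):
            if step(1, m0):
                return True
    return False


# --- AIC model selection ---------------------------------------------------

ORACLE_SUBSETS = tuple(
    frozenset(c) for r in range(4) for c in combinations(("X", "s", "n"), r)
)


def _oracle_design(x, cov_df: pd.DataFrame, subset: frozenset[str]) -> np.ndarray:
    # fixed order: intercept, batch, X, sex, nationality
    n = len(cov_df)
    out = [np.ones(n)]
    bd = pd.get_dummies(cov_df["batch"].astype(str), drop_first=True)
    out += [bd[c].to_numpy(dtype=float) for c in sorted(bd.columns)]
    if "X" in subset:
        out.append(np.asarray(x, dtype=float))
    if "s" in subset:
        sd = pd.get_dummies(cov_df["sex"].astype(str), drop_first=True)
        out += [sd[c].to_numpy(dtype=float) for c in sorted(sd.columns)]
    if "n" in subset:
        nd = pd.get_dummies(cov_df["nationality"].astype(str), drop_first=True)
        out += [nd[c].to_numpy(dtype=float) for c in sorted(nd.columns)]
    return np.column_stack(out)


def oracle_best_subset(y, x, cov_df: pd.DataFrame) -> frozenset[str]:
    """Argmin over an independently coded enumeration of all 8 OLS fits,
    using statsmodels for the likelihood, with the package's tie-break."""
    fits = []
    for subset in ORACLE_SUBSETS:
        design = _oracle_design(x, cov_df, subset)
        res = sm.OLS(np.asarray(y, dtype=float), design).fit()
        k = design.shape[1] + 1
        aic = 2 * k - 2 * res.llf
        fits.append((aic, k, "X" in subset, tuple(sorted(subset)), subset))
    return min(fits)[4]


# --- dense PLS (NIPALS) ----------------------------------------------------

def nipals_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
               tol: float = 1e-13, max_iter: int = 5000):
    """Classic NIPALS PLS regression on standardized blocks; returns
    (x_weights, y_weights) with unit-norm columns."""

    def standardize(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        return (M - mu) / sd

    Xc = standardize(np.asarray(X, dtype=float))
    Yc = standardize(np.asarray(Y, dtype=float))
    Us, Vs = [], []
    for _ in range(n_components):
        u = Yc[:, [int(np.argmax(Yc.var(axis=0)))]]
        for _ in range(max_iter):
            w = Xc.T @ u
            w = w / np.linalg.norm(w)
            t = Xc @ w
            c = Yc.T @ t
            c = c / np.linalg.norm(c)
            u_new = Yc @ c
            if np.linalg.norm(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        tt = float((t * t).sum())
        p_load = Xc.T @ t / tt
        c_reg = Yc.T @ t / tt
        Xc = Xc - t @ p_load.T
        Yc = Yc - t @ c_reg.T
        Us.append(w.ravel())
        Vs.append((c / np.linalg.norm(c)).ravel())
    return np.array(Us).T, np.array(Vs).T


# --- hypergeometric --------------------------------------------------------

def oracle_hypergeom_upper_tail(M: int, n_success: int, N: int, observed: int) -> float:
    """P(Obs >= observed) by direct summation of the hypergeometric mass."""
    total = math.comb(M, N)
    acc = 0
    for k in range(observed, min(n_success, N) + 1):
        if N - k > M - n_success:
            continue
        acc += math.comb(n_success, k) * math.comb(M - n_success, N - k)
    return acc / total
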