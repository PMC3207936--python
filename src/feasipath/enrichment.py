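"""Hypergeometric over-representation testing against named gene sets.

Given a selected gene list (e.g. diet-correlated genes) and a collection of
pathway gene sets over a common universe, each set is scored with the
upper-tail hypergeometric probability of drawing at least the observed number
of selected genes when ``set_size`` genes are drawn without replacement from a
universe containing ``|selected|`` successes.  Raw p-values are reported by
default (matching the usual over-representation convention); an optional
Benjamini-Hochberg column is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets intersected with a gene universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        clipped = {}
        for name, genes in self.sets.items():
            inside = frozenset(genes) & self.universe
            dropped = len(genes) - len(inside)
            if dropped:
                logger.info("gene set %r: dropping %d out-of-universe members", name, dropped)
            clipped[name] = inside
        object.__setattr__(self, "sets", clipped)


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated genes)."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
        sets[cells[0]] = frozenset(g for g in cells[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def hypergeometric_enrichment(
    selected,
    collection: GeneSetCollection,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set in the collection.

    Returns a table with term, expected count, observed count, set size and
    p-value (P(Obs >= observed)), sorted by p-value then term.  Expected count
    is ``set_size * |selected| / |universe|``.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty gene universe")
    selected = frozenset(selected)
    outside = selected - universe
    if outside:
        logger.info("dropping %d selected genes outside the universe", len(outside))
        selected = selected & universe
    rows = []
    M, n_success = len(universe), len(selected)
    for term in sorted(collection.sets):
        genes = collection.sets[term]
        N = len(genes)
        observed = len(selected & genes)
        expected = N * n_success / M
        # P(Obs >= observed) drawing N genes from a universe with n_success successes
        p = float(stats.hypergeom.sf(observed - 1, M, n_success, N))
        p = min(p, 1.0)
        rows.append((term, expected, observed, N, p))
    out = pd.DataFrame(
        rows, columns=["term", "expected_count", "observed_count", "set_size", "p_value"]
    ).sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    if bh_correction:
        m = len(out)
        order = out["p_value"].rank(method="first")
        bh = (out["p_value"] * m / order).to_numpy()
        # enforce monotonicity from the largest p downward
        idx = out["p_value"].argsort()[::-1]
        running = 1.0
        adj = bh.copy()
        for i in idx:
            running = min(running, bh[i])
            adj[i] = running
        out["p_bh"] = adj.clip(max=1.0)
    return out
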