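"""Latent-variable association between phenotype blocks and gene expression.

Two decompositions are provided.  Sparse partial least squares (sPLS,
regression mode) relates a predictor block — dietary variables plus dummy-coded
sex/nationality/batch — to gene expression, selecting per-dimension subsets of
variables by soft-thresholded singular pairs.  Regularized canonical
correlation analysis (rCCA) relates plasma-marker blocks to expression in a
symmetric fashion, stabilizing the within-block covariances with ridge terms
so that p >> n blocks remain solvable.

Both feed a similarity network: for each (phenotype variable, gene) pair the
similarity score is the sum over retained dimensions of the product of the two
variables' correlations with the latent variate, a rank-H bilinear
approximation of the cross-correlation matrix.  Pairs with |score| above a
threshold form the association network; a sample-label permutation test
calibrates how many genes pass by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import SampleCovariates

__all__ = [
    "PhenotypeBlock",
    "LatentDecomposition",
    "SimilarityNetwork",
    "transform_block",
    "dummy_code_covariates",
    "spls_fit",
    "spls_predict",
    "select_dimensions",
    "rcca_fit",
    "estimate_regularization",
    "similarity_network",
    "permutation_null",
    "Q2_LIMIT",
]

logger = logging.getLogger(__name__)

# Tenenhaus convention: a dimension contributes predictive power when Q2 >= 0.0975.
Q2_LIMIT = 0.0975


@dataclass(frozen=True)
class PhenotypeBlock:
    """Transformed and standardized samples x variables table."""

    data: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def transform_block(raw: pd.DataFrame) -> PhenotypeBlock:
    """Normalize each variable with the skewness-minimizing transform, then standardize.

    Candidates are identity, sqrt (non-negative columns) and log (strictly
    positive columns); the transform with the smallest absolute sample skewness
    wins, and the choice is recorded per variable.
    """
    data = {}
    transforms, means, sds = {}, {}, {}
    for col in raw.columns:
        values = pd.to_numeric(raw[col], errors="coerce")
        if values.isna().any():
            raise ValueError(f"phenotype column {col!r} is not numeric")
        v = values.to_numpy(dtype=float)
        candidates: dict[str, np.ndarray] = {"identity": v}
        if np.all(v >= 0):
            candidates["sqrt"] = np.sqrt(v)
        if np.all(v > 0):
            candidates["log"] = np.log(v)
        best = min(
            candidates,
            key=lambda name: (abs(float(stats.skew(candidates[name]))), name),
        )
        tv = candidates[best]
        mu, sd = float(np.mean(tv)), float(np.std(tv, ddof=1))
        if sd == 0:
            raise ValueError(f"phenotype column {col!r} is constant")
        data[col] = (tv - mu) / sd
        transforms[col], means[col], sds[col] = best, mu, sd
    return PhenotypeBlock(
        data=pd.DataFrame(data, index=raw.index),
        transforms=transforms,
        means=means,
        sds=sds,
    )


def dummy_code_covariates(cov: SampleCovariates) -> pd.DataFrame:
    """Treatment-contrast dummy columns for batch/sex/nationality, standardized."""
    out = {}
    for name in ("batch", "sex", "nationality"):
        levels = sorted(map(str, cov.table[name].unique()))
        vals = cov.table[name].astype(str)
        for level in levels[1:]:
            col = (vals == level).astype(float).to_numpy()
            sd = float(np.std(col, ddof=1))
            if sd == 0:
                continue
            out[f"{name}[{level}]"] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=cov.table.index)


@dataclass(frozen=True)
class LatentDecomposition:
    """Shared container for sPLS and rCCA fits."""

    mode: str  # "spls" | "rcca"
    x_names: tuple[str, ...]
    y_names: tuple[str, ...]
    x_weights: np.ndarray  # (p, H), unit-norm columns
    y_weights: np.ndarray  # (q, H), unit-norm columns
    x_variates: np.ndarray  # (n, H)
    y_variates: np.ndarray  # (n, H)
    n_components: int
    # standardization of the training blocks (needed for prediction)
    x_means: np.ndarray = field(default=None, repr=False)
    x_sds: np.ndarray = field(default=None, repr=False)
    y_means: np.ndarray = field(default=None, repr=False)
    y_sds: np.ndarray = field(default=None, repr=False)
    x_loadings: np.ndarray = field(default=None, repr=False)  # sPLS: P (p, H)
    y_coefficients: np.ndarray = field(default=None, repr=False)  # sPLS: C (q, H)
    q2: tuple[float, ...] = ()
    canonical_correlations: tuple[float, ...] = ()
    regularization: tuple[float, float] | None = None


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd, mu, sd


def _fix_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic orientation: largest-|.| entry of the X weight is positive.
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        return -u, -v
    return u, v


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|.| entries, soft-thresholding them by the
    magnitude of the largest excluded entry (mixOmics-style sparsity)."""
    p = w.size
    if keep >= p:
        return w
    order = np.argsort(-np.abs(w), kind="stable")
    lam = abs(w[order[keep]])
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    out[order[keep:]] = 0.0
    return out


def _as_matrix(block) -> tuple[np.ndarray, tuple[str, ...], list]:
    if isinstance(block, PhenotypeBlock):
        block = block.data
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), tuple(map(str, block.columns)), list(block.index)
    M = np.asarray(block, dtype=float)
    return M, tuple(f"v{i}" for i in range(M.shape[1])), list(range(M.shape[0]))


def spls_fit(
    X,
    Y,
    n_components: int = 2,
    keep_x: int | list[int] | None = None,
    keep_y: int | list[int] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> LatentDecomposition:
    """Regression-mode sparse PLS between predictor block X and responses Y.

    Per dimension, the dominant singular pair of the current cross-covariance
    is found by alternating power iterations; after each update, all but the
    ``keep_x`` (``keep_y``) largest-magnitude weight entries are zeroed with a
    soft threshold.  Both blocks are deflated by regression on the X variate.
    With full keeps the fit reduces exactly to dense PLS regression.
    """
    Xm, x_names, x_idx = _as_matrix(X)
    Ym, y_names, y_idx = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError(f"sample mismatch: X has {Xm.shape[0]} rows, Y has {Ym.shape[0]}")
    if list(x_idx) != list(y_idx):
        raise ValueError("X and Y sample identifiers are not aligned")
    n, p = Xm.shape
    q = Ym.shape[1]
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} outside [1, min(p={p}, n-1={n - 1})]"
        )
    keep_x_list = _expand_keep(keep_x, p, n_components, "keep_x")
    keep_y_list = _expand_keep(keep_y, q, n_components, "keep_y")

    Xc, x_mu, x_sd = _standardize(Xm)
    Yc, y_mu, y_sd = _standardize(Ym)
    Xd, Yd = Xc.copy(), Yc.copy()
    U = np.zeros((p, n_components))
    V = np.zeros((q, n_components))
    Xi = np.zeros((n, n_components))
    Om = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))

    for h in range(n_components):
        M = Xd.T @ Yd
        # initialize from the dominant right singular vector of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = M @ v
            u_new = _soft_threshold_keep(u_new, keep_x_list[h])
            nrm = np.linalg.norm(u_new)
            if nrm == 0:
                raise ValueError(f"dimension {h + 1}: X weight collapsed to zero")
            u_new /= nrm
            v_new = M.T @ u_new
            v_new = _soft_threshold_keep(v_new, keep_y_list[h])
            nrm = np.linalg.norm(v_new)
            if nrm == 0:
                raise ValueError(f"dimension {h + 1}: Y weight collapsed to zero")
            v_new /= nrm
            if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        u, v = _fix_sign(u, v)
        xi = Xd @ u
        om = Yd @ v
        denom = float(xi @ xi)
        if denom == 0:
            raise ValueError(f"dimension {h + 1}: degenerate X variate")
        ph = Xd.T @ xi / denom
        ch = Yd.T @ xi / denom
        Xd = Xd - np.outer(xi, ph)
        Yd = Yd - np.outer(xi, ch)  # regression mode: Y deflated by the X variate
        U[:, h], V[:, h], Xi[:, h], Om[:, h], P[:, h], C[:, h] = u, v, xi, om, ph, ch

    return LatentDecomposition(
        mode="spls",
        x_names=x_names,
        y_names=y_names,
        x_weights=U,
        y_weights=V,
        x_variates=Xi,
        y_variates=Om,
        n_components=n_components,
        x_means=x_mu,
        x_sds=x_sd,
        y_means=y_mu,
        y_sds=y_sd,
        x_loadings=P,
        y_coefficients=C,
    )


def _expand_keep(keep, total: int, h: int, name: str) -> list[int]:
    if keep is None:
        return [total] * h
    if isinstance(keep, int):
        keep = [keep] * h
    keep = list(keep)
    if len(keep) != h:
        raise ValueError(f"{name} must have one entry per dimension")
    for k in keep:
        if not 1 <= k <= total:
            raise ValueError(f"{name} entries must be in [1, {total}], got {k}")
    return keep


def spls_predict(decomp: LatentDecomposition, X_new, n_components: int | None = None) -> np.ndarray:
    """Predict responses (on the original Y scale) from a fitted sPLS model."""
    if decomp.mode != "spls":
        raise ValueError("prediction requires an sPLS decomposition")
    H = decomp.n_components if n_components is None else n_components
    Xm, _, _ = _as_matrix(X_new)
    Xc = (Xm - decomp.x_means) / decomp.x_sds
    U, Pl, C = decomp.x_weights[:, :H], decomp.x_loadings[:, :H], decomp.y_coefficients[:, :H]
    # W* = U (P'U)^-1 maps X to variates under the deflation scheme
    W_star = U @ np.linalg.inv(Pl.T @ U)
    Yc_hat = Xc @ W_star @ C.T
    return Yc_hat * decomp.y_sds + decomp.y_means


def _kfold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def select_dimensions(
    X,
    Y,
    max_components: int = 5,
    folds: int = 5,
    keep_x=None,
    keep_y=None,
    limit: float = Q2_LIMIT,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Retain sPLS dimensions while the cross-validated Q2_h stays above ``limit``.

    Q2_h = 1 - PRESS_h / RSS_{h-1}: the h-th dimension's out-of-sample gain
    relative to the residual variation left by the first h-1 dimensions.  At
    least one dimension is always retained (floor rule), so a pure-noise fit
    records its sub-limit Q2_1 but still yields H = 1.
    """
    if folds < 2:
        raise ValueError("at least 2 cross-validation folds required")
    Xm, _, _ = _as_matrix(X)
    Ym, _, _ = _as_matrix(Y)
    n = Xm.shape[0]
    rng = np.random.default_rng(seed)
    fold_idx = _kfold_indices(n, folds, rng)
    Yc, _, _ = _standardize(Ym)

    q2: list[float] = []
    for h in range(1, max_components + 1):
        press = 0.0
        for test in fold_idx:
            train = np.setdiff1d(np.arange(n), test)
            fit = spls_fit(
                Xm[train], Ym[train], n_components=h,
                keep_x=_subset_keep(keep_x, h), keep_y=_subset_keep(keep_y, h),
            )
            pred = spls_predict(fit, Xm[test], n_components=h)
            # compare on the standardized-Y scale of the full data
            resid = (Ym[test] - pred) / np.where(Ym.std(axis=0, ddof=1) == 0, 1, Ym.std(axis=0, ddof=1))
            press += float(np.sum(resid**2))
        if h == 1:
            rss_prev = float(np.sum(Yc**2))
        else:
            fit_prev = spls_fit(
                Xm, Ym, n_components=h - 1,
                keep_x=_subset_keep(keep_x, h - 1), keep_y=_subset_keep(keep_y, h - 1),
            )
            pred_prev = spls_predict(fit_prev, Xm, n_components=h - 1)
            resid_prev = (Ym - pred_prev) / np.where(
                Ym.std(axis=0, ddof=1) == 0, 1, Ym.std(axis=0, ddof=1)
            )
            rss_prev = float(np.sum(resid_prev**2))
        q2.append(1.0 - press / rss_prev if rss_prev > 0 else -np.inf)
        if q2[-1] < limit:
            break
    # retain the leading streak of dimensions with Q2 >= limit; floor at 1
    streak = 0
    for v in q2:
        if v >= limit:
            streak += 1
        else:
            break
    H = max(1, streak)
    logger.info("Q2 per dimension: %s -> retaining %d", [round(v, 4) for v in q2], H)
    return H, q2


def _subset_keep(keep, h):
    if keep is None or isinstance(keep, int):
        return keep
    return list(keep)[:h]


def rcca_fit(X, Y, lambda1: float, lambda2: float, n_components: int = 2) -> LatentDecomposition:
    """Ridge-regularized CCA via whitened cross-covariance SVD.

    Canonical weights solve the generalized eigenproblem built from
    (Sxx + lambda1 I) and (Syy + lambda2 I); regularization keeps the problem
    well-posed when variables outnumber samples.  Canonical correlations are
    returned in non-increasing order.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization parameters must be non-negative")
    Xm, x_names, x_idx = _as_matrix(X)
    Ym, y_names, y_idx = _as_matrix(Y)
    if list(x_idx) != list(y_idx):
        raise ValueError("X and Y sample identifiers are not aligned")
    n, p = Xm.shape
    q = Ym.shape[1]
    if not 1 <= n_components <= min(p, q):
        raise ValueError(f"n_components={n_components} outside [1, min(p, q)]")
    Xc, x_mu, x_sd = _standardize(Xm)
    Yc, y_mu, y_sd = _standardize(Ym)
    Sxx = Xc.T @ Xc / (n - 1) + lambda1 * np.eye(p)
    Syy = Yc.T @ Yc / (n - 1) + lambda2 * np.eye(q)
    Sxy = Xc.T @ Yc / (n - 1)
    try:
        Lx = np.linalg.cholesky(Sxx)
        Ly = np.linalg.cholesky(Syy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular regularized covariance; increase lambda1/lambda2 above 0"
        ) from exc
    K = np.linalg.solve(Lx, Sxy) @ np.linalg.inv(Ly).T
    Uw, d, Vt = np.linalg.svd(K, full_matrices=False)
    A = np.linalg.solve(Lx.T, Uw[:, :n_components])
    B = np.linalg.solve(Ly.T, Vt[:n_components].T)
    # unit-norm weight columns with deterministic sign
    for h in range(n_components):
        a, b = A[:, h], B[:, h]
        a = a / np.linalg.norm(a)
        b = b / np.linalg.norm(b)
        a, b = _fix_sign(a, b)
        A[:, h], B[:, h] = a, b
    Xi = Xc @ A
    Om = Yc @ B
    cors = []
    for h in range(n_components):
        denom = np.linalg.norm(Xi[:, h]) * np.linalg.norm(Om[:, h])
        cors.append(float(Xi[:, h] @ Om[:, h] / denom) if denom > 0 else 0.0)
    return LatentDecomposition(
        mode="rcca",
        x_names=x_names,
        y_names=y_names,
        x_weights=A,
        y_weights=B,
        x_variates=Xi,
        y_variates=Om,
        n_components=n_components,
        x_means=x_mu,
        x_sds=x_sd,
        y_means=y_mu,
        y_sds=y_sd,
        canonical_correlations=tuple(min(1.0, max(c, -1.0)) for c in cors),
        regularization=(lambda1, lambda2),
    )


def estimate_regularization(
    X,
    Y,
    grid1,
    grid2,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid-search (lambda1, lambda2) maximizing the mean held-out first
    canonical correlation; ties prefer smaller lambda1, then smaller lambda2."""
    Xm, _, _ = _as_matrix(X)
    Ym, _, _ = _as_matrix(Y)
    grid1, grid2 = sorted(set(map(float, grid1))), sorted(set(map(float, grid2)))
    if not grid1 or not grid2:
        raise ValueError("regularization grid is empty")
    n = Xm.shape[0]
    rng = np.random.default_rng(seed)
    fold_idx = _kfold_indices(n, folds, rng)
    best, best_score = None, -np.inf
    for l1 in grid1:
        for l2 in grid2:
            scores = []
            for test in fold_idx:
                train = np.setdiff1d(np.arange(n), test)
                if len(test) < 3:
                    continue
                try:
                    fit = rcca_fit(Xm[train], Ym[train], l1, l2, n_components=1)
                except np.linalg.LinAlgError:
                    scores.append(-np.inf)
                    continue
                Xt = (Xm[test] - decomp_means(fit, "x")) / fit.x_sds
                Yt = (Ym[test] - decomp_means(fit, "y")) / fit.y_sds
                xi = Xt @ fit.x_weights[:, 0]
                om = Yt @ fit.y_weights[:, 0]
                if np.std(xi) == 0 or np.std(om) == 0:
                    scores.append(0.0)
                else:
                    scores.append(abs(float(np.corrcoef(xi, om)[0, 1])))
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score + 1e-12:
                best, best_score = (l1, l2), score
    return best


def decomp_means(fit: LatentDecomposition, which: str) -> np.ndarray:
    return fit.x_means if which == "x" else fit.y_means


@dataclass(frozen=True)
class SimilarityNetwork:
    """Thresholded bipartite (phenotype variable, gene) association pairs."""

    pairs: pd.DataFrame  # columns: variable, gene, score, sign
    threshold: float
    mode: str

    def genes_for(self, variable: str) -> list[str]:
        sel = self.pairs[self.pairs["variable"] == variable]
        return sorted(sel["gene"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.pairs["gene"].unique())


def _variate_basis(decomp: LatentDecomposition) -> np.ndarray:
    """Orthonormal basis of the retained latent space used for projection.

    sPLS X-variates are mutually orthogonal by deflation; rCCA variates are
    only covariance-orthogonal, so the compromise variates (xi + omega)/2 are
    QR-orthonormalized.  Orthonormality guarantees similarity scores stay in
    [-1, 1] (Bessel + Cauchy-Schwarz).
    """
    if decomp.mode == "spls":
        Z = decomp.x_variates.copy()
    else:
        Z = (decomp.x_variates + decomp.y_variates) / 2.0
    Z = Z - Z.mean(axis=0)
    Q, R = np.linalg.qr(Z)
    # keep the orientation of the original variates
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def similarity_network(
    decomp: LatentDecomposition,
    threshold: float = 0.7,
    X=None,
    Y=None,
) -> SimilarityNetwork:
    """Bilinear similarity scores, thresholded into an association network.

    score(i, j) = sum_h corr(x_i, variate_h) * corr(y_j, variate_h) over the
    retained dimensions.  Pairs with |score| > threshold are returned with
    their sign.  Centered variable vectors are correlated against an
    orthonormalized variate basis, so |score| <= 1 up to rounding.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if X is None or Y is None:
        raise ValueError("similarity_network needs the X and Y data blocks")
    Xm, x_names, _ = _as_matrix(X)
    Ym, y_names, _ = _as_matrix(Y)
    Q = _variate_basis(decomp)

    def _cor_block(M: np.ndarray) -> np.ndarray:
        Mc = M - M.mean(axis=0)
        norms = np.linalg.norm(Mc, axis=0)
        norms = np.where(norms == 0, 1.0, norms)
        return (Mc / norms).T @ Q  # columns of Q are unit-norm, centered

    Cx = _cor_block(Xm)
    Cy = _cor_block(Ym)
    S = Cx @ Cy.T
    rows = []
    for i, var in enumerate(x_names):
        for j, gene in enumerate(y_names):
            s = float(S[i, j])
            if abs(s) > threshold:
                rows.append((var, gene, s, 1 if s >= 0 else -1))
    pairs = pd.DataFrame(rows, columns=["variable", "gene", "score", "sign"])
    pairs = pairs.sort_values(["variable", "gene"], kind="stable").reset_index(drop=True)
    logger.info(
        "similarity network: %d pairs over threshold %.2f (%d genes)",
        len(pairs), threshold, pairs["gene"].nunique() if len(pairs) else 0,
    )
    return SimilarityNetwork(pairs=pairs, threshold=threshold, mode=decomp.mode)


def permutation_null(
    X,
    Y,
    n_permutations: int = 100,
    threshold: float = 0.7,
    seed: int = 0,
    focal_variable: str | None = None,
    n_components: int = 2,
    keep_x=None,
    keep_y=None,
) -> dict:
    """Sample-label permutation null for the similarity-network gene count.

    Each replicate permutes the rows of the X block (breaking the X-Y sample
    pairing while preserving both blocks' internal structure), refits the sPLS
    decomposition and counts genes passing the similarity threshold for the
    focal variable (or any variable when none is named).  Replicate seeds are
    derived from ``seed`` by counter offset, so runs are reproducible.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xm, x_names, _ = _as_matrix(X)
    Ym, _, _ = _as_matrix(Y)
    counts = []
    for r in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), r]))
        perm = rng.permutation(Xm.shape[0])
        Xp = Xm[perm]
        Xp_df = pd.DataFrame(Xp, columns=list(x_names))
        fit = spls_fit(Xp_df, Ym, n_components=n_components, keep_x=keep_x, keep_y=keep_y)
        net = similarity_network(fit, threshold=threshold, X=Xp_df, Y=Y)
        if focal_variable is not None:
            counts.append(len(net.genes_for(focal_variable)))
        else:
            counts.append(len(net.genes))
    counts_arr = np.asarray(counts)
    return {
        "counts": counts,
        "mean": float(counts_arr.mean()),
        "median": float(np.median(counts_arr)),
        "n_permutations": n_permutations,
        "threshold": threshold,
        "seed": int(seed),
        "focal_variable": focal_variable,
    }
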