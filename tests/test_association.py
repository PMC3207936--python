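"""Phenotype transforms, sPLS/rCCA decompositions and similarity networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import feasipath as fp
from feasipath.association import (
    _standardize,
    estimate_regularization,
    rcca_fit,
    similarity_network,
    spls_fit,
)
from oracles import nipals_pls


def _df(M, prefix="v"):
    M = np.asarray(M, dtype=float)
    return pd.DataFrame(
        M,
        index=[f"S{i}" for i in range(M.shape[0])],
        columns=[f"{prefix}{j}" for j in range(M.shape[1])],
    )


# --- transform_block -------------------------------------------------------

def test_transform_symmetric_column_stays_identity():
    rng = np.random.default_rng(0)
    block = fp.transform_block(_df(rng.normal(0, 1, (200, 1))))
    assert block.transforms["v0"] == "identity"


def test_transform_lognormal_column_gets_log():
    rng = np.random.default_rng(1)
    block = fp.transform_block(_df(np.exp(rng.normal(0, 1, (200, 1)))))
    assert block.transforms["v0"] == "log"


def test_transform_zero_values_exclude_log():
    rng = np.random.default_rng(2)
    v = np.abs(rng.normal(0, 1, (100, 1)))
    v[0] = 0.0
    block = fp.transform_block(_df(v**2))
    assert block.transforms["v0"] in {"identity", "sqrt"}


def test_transform_standardizes_columns():
    rng = np.random.default_rng(3)
    raw = _df(np.column_stack([rng.normal(5, 3, 50), np.exp(rng.normal(0, 1, 50))]))
    block = fp.transform_block(raw)
    assert np.allclose(block.data.mean(axis=0), 0, atol=1e-8)
    assert np.allclose(block.data.std(axis=0, ddof=1), 1, atol=1e-8)


def test_transform_rejects_non_numeric():
    raw = pd.DataFrame({"v0": ["a", "b", "c"]})
    with pytest.raises(ValueError, match="v0"):
        fp.transform_block(raw)


def test_transform_minimizes_absolute_skewness():
    rng = np.random.default_rng(4)
    v = np.exp(rng.normal(0, 1, 300))
    block = fp.transform_block(_df(v.reshape(-1, 1)))
    sk = {
        "identity": abs(stats.skew(v)),
        "sqrt": abs(stats.skew(np.sqrt(v))),
        "log": abs(stats.skew(np.log(v))),
    }
    assert block.transforms["v0"] == min(sk, key=sk.get)


# --- sPLS ------------------------------------------------------------------

def test_spls_full_keep_equals_dense_pls():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 6))
    Y = rng.normal(size=(30, 9))
    Y[:, 0] += 1.2 * X[:, 0]
    fit = spls_fit(X, Y, n_components=3)
    U, V = nipals_pls(X, Y, 3)
    for h in range(3):
        du = min(
            np.abs(fit.x_weights[:, h] - U[:, h]).max(),
            np.abs(fit.x_weights[:, h] + U[:, h]).max(),
        )
        dv = min(
            np.abs(fit.y_weights[:, h] - V[:, h]).max(),
            np.abs(fit.y_weights[:, h] + V[:, h]).max(),
        )
        assert du < 1e-8 and dv < 1e-8


def test_spls_collinear_variable_carries_dimension():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(40, 5))
    Y = np.column_stack([X[:, 2] * 2.0, rng.normal(size=40) * 0.01])
    fit = spls_fit(X, Y, n_components=1, keep_x=1)
    w = fit.x_weights[:, 0]
    assert np.argmax(np.abs(w)) == 2
    assert np.count_nonzero(w) == 1
    assert abs(abs(w[2]) - 1) < 1e-10


def test_spls_x_variates_orthogonal():
    rng = np.random.default_rng(7)
    fit = spls_fit(rng.normal(size=(25, 8)), rng.normal(size=(25, 10)), n_components=4)
    G = fit.x_variates.T @ fit.x_variates
    assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8


def test_spls_rejects_misaligned_samples():
    X = _df(np.eye(4))
    Y = _df(np.eye(4))
    Y.index = [f"T{i}" for i in range(4)]
    with pytest.raises(ValueError, match="aligned"):
        spls_fit(X, Y, n_components=1)


def test_spls_rejects_too_many_components():
    rng = np.random.default_rng(8)
    with pytest.raises(ValueError, match="n_components"):
        spls_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)), n_components=5)


# --- dimension selection ---------------------------------------------------

def _planted(rng, n, q, factors):
    ts = [rng.normal(size=n) for _ in range(factors)]
    X = np.column_stack(ts + [rng.normal(size=n) for _ in range(3)])
    Y = sum(np.outer(t, rng.normal(size=q)) for t in ts) + 0.3 * rng.normal(size=(n, q))
    return X, Y


def test_q2_selects_one_strong_factor():
    rng = np.random.default_rng(9)
    X, Y = _planted(rng, 60, 8, 1)
    H, q2 = fp.select_dimensions(X, Y, max_components=3, seed=1)
    assert H == 1
    assert q2[0] > 0.0975


def test_q2_selects_two_orthogonal_factors():
    rng = np.random.default_rng(10)
    X, Y = _planted(rng, 80, 10, 2)
    H, _ = fp.select_dimensions(X, Y, max_components=4, seed=1)
    assert H == 2


def test_q2_floor_on_pure_noise():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(40, 5))
    Y = rng.normal(size=(40, 8))
    H, q2 = fp.select_dimensions(X, Y, max_components=3, seed=1)
    assert H == 1
    assert q2[0] < 0.0975


# --- rCCA ------------------------------------------------------------------

def test_rcca_identical_blocks_give_unit_correlations():
    rng = np.random.default_rng(12)
    Z = rng.normal(size=(20, 4))
    fit = rcca_fit(Z, Z.copy(), 0.0, 0.0, n_components=3)
    assert np.allclose(fit.canonical_correlations, 1.0, atol=1e-8)


def test_rcca_correlations_bounded_and_sorted():
    rng = np.random.default_rng(13)
    fit = rcca_fit(rng.normal(size=(30, 6)), rng.normal(size=(30, 8)), 0.05, 0.05, 4)
    c = np.array(fit.canonical_correlations)
    assert np.all((0 <= c) & (c <= 1))
    assert np.all(np.diff(c) <= 1e-12)


def test_rcca_singular_without_regularization():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(10, 20))  # p > n
    Y = rng.normal(size=(10, 4))
    with pytest.raises(np.linalg.LinAlgError, match="lambda"):
        rcca_fit(X, Y, 0.0, 0.0, n_components=2)


def test_rcca_large_lambda_limit_is_cross_covariance_svd():
    # planted factors of distinct strength give the cross-covariance a clean
    # spectral gap, so the finite-lambda weights sit within 1e-6 of the limit
    rng = np.random.default_rng(15)
    t1, t2 = rng.normal(size=25), rng.normal(size=25)
    X = np.column_stack([t1, t2, rng.normal(size=(25, 3))])
    Y = np.column_stack(
        [2.0 * t1 + 0.1 * rng.normal(size=25), 0.8 * t2 + 0.1 * rng.normal(size=25),
         rng.normal(size=(25, 5)) * 0.1]
    )
    fit = rcca_fit(X, Y, 1e6, 1e6, n_components=2)
    Xc, _, _ = _standardize(X)
    Yc, _, _ = _standardize(Y)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc / 24)
    for h in range(2):
        da = min(
            np.abs(fit.x_weights[:, h] - U[:, h]).max(),
            np.abs(fit.x_weights[:, h] + U[:, h]).max(),
        )
        db = min(
            np.abs(fit.y_weights[:, h] - Vt[h]).max(),
            np.abs(fit.y_weights[:, h] + Vt[h]).max(),
        )
        assert da < 1e-6 and db < 1e-6


def test_estimate_regularization_single_point_and_determinism():
    rng = np.random.default_rng(16)
    t = rng.normal(size=30)
    X = np.column_stack([t, rng.normal(size=30)])
    Y = np.column_stack([t + 0.2 * rng.normal(size=30), rng.normal(size=(30, 2))])
    assert estimate_regularization(X, Y, [0.5], [0.25], seed=3) == (0.5, 0.25)
    a = estimate_regularization(X, Y, [1e-4, 1e-2, 1], [1e-4, 1e-2, 1], seed=3)
    b = estimate_regularization(X, Y, [1e-4, 1e-2, 1], [1e-4, 1e-2, 1], seed=3)
    assert a == b
    noise = estimate_regularization(
        rng.normal(size=(15, 3)), rng.normal(size=(15, 3)), [1e-2, 1], [1e-2, 1], seed=3
    )
    assert noise in {(l1, l2) for l1 in (1e-2, 1.0) for l2 in (1e-2, 1.0)}


# --- similarity networks ---------------------------------------------------

def test_similarity_perfect_pair_scores_near_one():
    rng = np.random.default_rng(17)
    t = rng.normal(size=40)
    X = _df(np.column_stack([t, rng.normal(size=(40, 2))]), "x")
    Y = _df(np.column_stack([t, rng.normal(size=(40, 3))]), "g")
    fit = spls_fit(X, Y, n_components=2)
    net = similarity_network(fit, threshold=0.7, X=X, Y=Y)
    row = net.pairs[(net.pairs.variable == "x0") & (net.pairs.gene == "g0")]
    assert len(row) == 1
    assert row.score.iloc[0] > 0.9 and row.sign.iloc[0] == 1


def test_similarity_scores_bounded():
    rng = np.random.default_rng(18)
    X = rng.normal(size=(20, 5))
    Y = rng.normal(size=(20, 12))
    for mode_fit in (
        spls_fit(X, Y, n_components=4),
        rcca_fit(X, Y, 0.1, 0.1, n_components=4),
    ):
        net = similarity_network(mode_fit, threshold=0.0, X=X, Y=Y)
        assert net.pairs.score.abs().max() <= 1 + 1e-8


def test_similarity_independent_noise_rarely_passes():
    rng = np.random.default_rng(19)
    passed = 0
    for _ in range(100):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 4))
        fit = spls_fit(X, Y, n_components=1)
        net = similarity_network(fit, threshold=0.7, X=X, Y=Y)
        passed += len(net.pairs) > 0
    assert passed <= 10


def test_similarity_threshold_monotonicity():
    rng = np.random.default_rng(20)
    t = rng.normal(size=30)
    X = _df(np.column_stack([t, rng.normal(size=(30, 2))]), "x")
    Y = _df(
        np.column_stack([t + 0.3 * rng.normal(size=30), rng.normal(size=(30, 5))]), "g"
    )
    fit = spls_fit(X, Y, n_components=2)
    lo = similarity_network(fit, threshold=0.70, X=X, Y=Y)
    hi = similarity_network(fit, threshold=0.75, X=X, Y=Y)
    lo_pairs = set(zip(lo.pairs.variable, lo.pairs.gene))
    hi_pairs = set(zip(hi.pairs.variable, hi.pairs.gene))
    assert hi_pairs <= lo_pairs


# --- permutation null ------------------------------------------------------

def test_permutation_null_deterministic_under_seed():
    rng = np.random.default_rng(21)
    X = _df(rng.normal(size=(19, 4)), "x")
    Y = _df(rng.normal(size=(19, 10)), "g")
    a = fp.permutation_null(X, Y, n_permutations=5, threshold=0.7, seed=99)
    b = fp.permutation_null(X, Y, n_permutations=5, threshold=0.7, seed=99)
    assert a["counts"] == b["counts"]


def test_permutation_breaks_planted_association():
    rng = np.random.default_rng(22)
    t = rng.normal(size=19)
    X = _df(np.column_stack([t, rng.normal(size=(19, 3))]), "x")
    Y = _df(
        np.column_stack(
            [t + 0.2 * rng.normal(size=19) for _ in range(5)]
            + [rng.normal(size=19) for _ in range(10)]
        ),
        "g",
    )
    fit = spls_fit(X, Y, n_components=2, keep_x=2)
    unperm = len(
        similarity_network(fit, threshold=0.7, X=X, Y=Y).genes_for("x0")
    )
    null = fp.permutation_null(
        X, Y, n_permutations=30, threshold=0.7, seed=7,
        focal_variable="x0", n_components=2, keep_x=2,
    )
    assert unperm >= 4
    assert unperm > null["mean"] + 3
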