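"""RDA against explicit hat-matrix oracles, outlier rule arithmetic, and
the candidate/non-candidate split."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from geacoia.data_io import GenotypeTable
from geacoia.rda_gea import (
    RDAResult,
    assign_driving_variable,
    detect_outlier_loci,
    ezekiel_adjusted_r2,
    run_rda,
    split_candidates,
)


def test_perfect_fit_r2_one(rng):
    x = rng.normal(size=20)
    Y = np.column_stack([2.0 * x + 1.0])
    res = run_rda(Y, x[:, None], n_perm=9, seed=0)
    assert res.r2 == pytest.approx(1.0)
    assert res.unconstrained_eigenvalues.sum() == pytest.approx(0.0, abs=1e-16)


def test_orthogonal_response_r2_zero(rng):
    x = rng.normal(size=30)
    x = (x - x.mean())
    y = rng.normal(size=30)
    y = y - y.mean()
    y -= x * (x @ y) / (x @ x)      # exact sample covariance 0
    res = run_rda(y[:, None], x[:, None], n_perm=9, seed=0)
    assert res.r2 == pytest.approx(0.0, abs=1e-10)


def test_ezekiel_adjusted_r2_arithmetic():
    assert ezekiel_adjusted_r2(0.5, n=10, q=2) == pytest.approx(1 - 0.5 * 9 / 7)
    assert ezekiel_adjusted_r2(0.5, n=10, q=2) == pytest.approx(0.35714, abs=5e-6)


def test_matches_hat_matrix_eigendecomposition_oracle(rng):
    Y = rng.integers(0, 3, size=(30, 50)).astype(float)
    X = rng.normal(size=(30, 3))
    res = run_rda(Y, X, n_perm=9, seed=0)
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    H = Xs @ np.linalg.inv(Xs.T @ Xs) @ Xs.T
    Yhat = H @ Yc
    w, V = np.linalg.eigh(Yhat.T @ Yhat / 29)
    w = w[::-1][:3]
    np.testing.assert_allclose(res.constrained_eigenvalues, w, rtol=1e-8)
    # loadings match the oracle eigenvectors up to sign
    for a in range(3):
        v = V[:, ::-1][:, a]
        dot = abs(v @ res.locus_loadings[:, a])
        assert dot == pytest.approx(1.0, abs=1e-8)
    # variance decomposition
    total = float((Yc ** 2).sum()) / 29
    assert res.constrained_eigenvalues.sum() + res.unconstrained_eigenvalues.sum() \
        == pytest.approx(total, rel=1e-8)
    assert res.r2 == pytest.approx(res.constrained_eigenvalues.sum() * 29
                                   / float((Yc ** 2).sum()), rel=1e-8)


def test_rda_on_own_principal_axes_reproduces_pca(rng):
    # constraining on a basis spanning the PCA scores leaves Y unchanged,
    # so constrained eigenvalues equal the PCA spectrum of Y
    Y = rng.normal(size=(20, 5))
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    res = run_rda(Y, U[:, :5], n_perm=9, seed=0)
    np.testing.assert_allclose(res.constrained_eigenvalues, s ** 2 / 19, rtol=1e-8)
    for a in range(5):
        assert abs(Vt[a] @ res.locus_loadings[:, a]) == pytest.approx(1.0, abs=1e-8)


def test_rank_deficient_predictors_error(rng):
    X = rng.normal(size=(20, 2))
    X = np.column_stack([X, X[:, 0] + X[:, 1]])
    with pytest.raises(ValueError, match="VIF"):
        run_rda(rng.normal(size=(20, 4)), X, n_perm=9)


def _loadings_result(loadings):
    loadings = np.asarray(loadings, dtype=float)
    k = loadings.shape[1]
    return RDAResult(
        constrained_eigenvalues=np.linspace(2, 1, k),
        unconstrained_eigenvalues=np.array([]), r2=0.5, adj_r2=0.4,
        individual_scores=np.empty((0, k)), locus_loadings=loadings,
        biplot_scores=np.empty((0, k)), pseudo_f=1.0, global_p=0.01,
        axis_f=np.ones(k), axis_p=np.full(k, 0.01), n_perm=9,
        locus_ids=np.array([f"L{j}" for j in range(loadings.shape[0])], dtype=object),
    )


def test_outliers_constant_loadings_empty():
    res = _loadings_result(np.ones((10, 1)))
    with pytest.warns(UserWarning, match="zero loading dispersion"):
        out = detect_outlier_loci(res, axes=[0])
    assert len(out) == 0


def test_outlier_direct_arithmetic():
    # nine zeros and a five: |5 - 0.5| = 4.5 exceeds 2.5 SD of the loadings
    res = _loadings_result(np.array([[0.0]] * 9 + [[5.0]]))
    out = detect_outlier_loci(res, axes=[0], sd_mult=2.5)
    assert list(out.index) == ["L9"]
    assert out.loc["L9", "axis"] == 0


def test_outlier_rate_matches_normal_tail(rng):
    load = rng.normal(size=(10000, 1))
    res = _loadings_result(load)
    out = detect_outlier_loci(res, axes=[0], sd_mult=2.5)
    expected = 2 * (1 - norm.cdf(2.5))
    assert len(out) / 10000 == pytest.approx(expected, abs=0.003)


def test_outlier_union_attributes_first_axis():
    load = np.zeros((20, 2))
    load[0, 0] = 10.0
    load[0, 1] = 10.0
    load[1, 1] = 10.0
    res = _loadings_result(load)
    out = detect_outlier_loci(res, axes=[0, 1], sd_mult=2.5)
    assert out.loc["L0", "axis"] == 0       # flagged on both, tagged to axis 0
    assert out.loc["L1", "axis"] == 1
    assert len(out) == 2


def _geno_from_dosage(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeTable(
        dosage, np.zeros_like(dosage, dtype=bool),
        [f"L{j}" for j in range(dosage.shape[1])],
        [f"i{i}" for i in range(dosage.shape[0])],
    )


def test_assign_driving_variable_noiseless_and_tie(rng):
    n = 40
    bio12 = np.repeat(np.linspace(0, 1, 8), 5)
    dos = np.clip(np.round(2 * bio12).astype(int), 0, 2)
    g = _geno_from_dosage(dos[:, None])
    clim = pd.DataFrame({"BIO12": bio12, "BIO01": rng.normal(size=n)},
                        index=g.individual_ids)
    out = assign_driving_variable(g, ["L0"], clim)
    assert out.loc["L0", "variable"] == "BIO12"
    # exact tie: two identical predictors -> lexicographically first name
    clim2 = pd.DataFrame({"BIOB": bio12, "BIOA": bio12}, index=g.individual_ids)
    out2 = assign_driving_variable(g, ["L0"], clim2)
    assert out2.loc["L0", "variable"] == "BIOA"


def test_assign_independent_locus_small_r(rng):
    n = 150
    g = _geno_from_dosage(rng.integers(0, 3, size=(n, 1)))
    clim = pd.DataFrame(rng.normal(size=(n, 3)), columns=["A", "B", "C"],
                        index=g.individual_ids)
    out = assign_driving_variable(g, ["L0"], clim)
    assert abs(out.loc["L0", "r"]) < 0.3


def test_split_candidates_bookkeeping(rng):
    g = _geno_from_dosage(rng.integers(0, 3, size=(20, 100)))
    cands = [f"L{j}" for j in range(10)]
    split = split_candidates(g, cands, seed=5)
    assert len(split.noncandidate_pool) == 90
    assert len(split.noncandidate_sample) == 10
    assert set(split.noncandidate_sample) <= set(split.noncandidate_pool)
    assert not set(split.noncandidate_sample) & set(cands)
    split2 = split_candidates(g, cands, seed=5)
    assert split.noncandidate_sample == split2.noncandidate_sample
    with pytest.raises(ValueError, match="pool"):
        split_candidates(g, [f"L{j}" for j in range(95)], seed=1)


def test_split_excludes_monomorphic_and_known_outliers(rng):
    dosage = rng.integers(0, 3, size=(20, 50))
    dosage[:, 40] = 1                                   # monomorphic locus
    g = _geno_from_dosage(dosage)
    split = split_candidates(g, [f"L{j}" for j in range(5)],
                             known_outliers=["L30"], seed=2)
    assert "L40" not in split.noncandidate_pool
    assert "L30" not in split.noncandidate_pool
    assert len(split.noncandidate_pool) == 50 - 5 - 1 - 1
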