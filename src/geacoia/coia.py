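"""Co-inertia analysis (CoIA) of two tables sharing the same individuals,
the RV coefficient with a row-permutation test, and a locus-resampling
bootstrap null for the RV.

CoIA is a symmetric two-table ordination: with uniform row weights 1/n and
column-centered tables X_A (n x p) and X_B (n x r), the co-inertia axes
are the left/right singular vectors of the cross-covariance
C = X_A' X_B / n, and the per-axis co-inertia is the squared singular
value.  The RV coefficient is the matrix correlation
trace(W_A W_B) / sqrt(trace(W_A^2) trace(W_B^2)) with W = X X' the row
cross-product operators; it lies in [0, 1] and generalizes the squared
Pearson correlation to two multivariate tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from geacoia.data_io import GenotypeTable, impute_and_center

__all__ = [
    "PCATriplet",
    "CoIAResult",
    "BootstrapRVNull",
    "pca_triplet",
    "coinertia",
    "rv_coefficient",
    "rv_permutation_test",
    "bootstrap_rv_null",
]


@dataclasses.dataclass
class PCATriplet:
    """A centered (optionally scaled) table with its PCA spectrum under
    uniform row weights 1/n (divisor-n covariance, the ade4 convention)."""

    data: np.ndarray                 # centered matrix, n x p
    eigenvalues: np.ndarray          # non-increasing
    components: np.ndarray           # p x rank, orthonormal columns
    retained_axes: int
    cumulative_variance: np.ndarray  # per-axis cumulative fraction
    scaled: bool
    row_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def truncated(self) -> np.ndarray:
        """Reconstruction of the table from the retained components."""
        Vm = self.components[:, : self.retained_axes]
        return (self.data @ Vm) @ Vm.T


@dataclasses.dataclass
class CoIAResult:
    per_axis_coinertia: np.ndarray   # squared singular values, non-increasing
    total_coinertia: float
    cum_coinertia_frac: np.ndarray
    rowscores_A: np.ndarray          # n x axes
    rowscores_B: np.ndarray          # n x axes
    loadings_A: np.ndarray           # p_A x axes
    loadings_B: np.ndarray           # p_B x axes
    rv: float
    rv_p: float
    n_perm: int
    truncated: bool
    individual_ids: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return len(self.per_axis_coinertia)


def pca_triplet(
    M: np.ndarray,
    retain: float = 0.90,
    scale: bool = False,
    row_ids: Sequence[str] | None = None,
) -> PCATriplet:
    """Center (optionally scale) M and decompose its column covariance.

    ``retain`` sets the number of kept axes: the smallest count whose
    cumulative eigenvalue fraction reaches the threshold.
    """
    if not 0.0 < retain <= 1.0:
        raise ValueError("retain must lie in (0, 1]")
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 1:
        raise ValueError("need >= 2 rows and >= 1 column")
    if np.isnan(M).any():
        raise ValueError("missing values must be imputed upstream")
    X = M - M.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot scale zero-variance columns")
        X = X / sd
    n = X.shape[0]
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / n
    tol = 1e-12 * max(eig[0], 1.0) if eig.size else 0.0
    rank = int(np.sum(eig > tol))
    eig = eig[:rank]
    V = Vt[:rank].T
    cum = np.cumsum(eig) / eig.sum()
    retained = int(np.searchsorted(cum, retain - 1e-12) + 1)
    return PCATriplet(
        data=X,
        eigenvalues=eig,
        components=V,
        retained_axes=retained,
        cumulative_variance=cum,
        scaled=scale,
        row_ids=np.asarray(row_ids, dtype=object) if row_ids is not None else None,
    )


def rv_coefficient(A: np.ndarray, B: np.ndarray) -> float:
    """RV coefficient of two column-centered tables on the same rows."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("tables must have the same number of rows")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = float(np.sum((A.T @ B) ** 2))
    den_a = float(np.sqrt(np.sum((A.T @ A) ** 2)))
    den_b = float(np.sqrt(np.sum((B.T @ B) ** 2)))
    if den_a == 0 or den_b == 0:
        raise ValueError("RV undefined for a zero table")
    return num / (den_a * den_b)


def rv_permutation_test(
    A: np.ndarray, B: np.ndarray, n_perm: int = 9999, seed: int | None = None,
) -> float:
    """One-sided p-value for RV(A, B) against random row alignment.

    Rows of B are permuted; p = (#{RV_perm >= RV_obs} + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rv_obs = rv_coefficient(A, B)
    B = np.asarray(B, dtype=float)
    exceed = 0
    for _ in range(n_perm):
        rv_p = rv_coefficient(A, B[rng.permutation(B.shape[0])])
        if rv_p >= rv_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def coinertia(
    A: PCATriplet,
    B: PCATriplet,
    truncate: bool = True,
    n_perm: int = 0,
    seed: int | None = None,
) -> CoIAResult:
    """Couple two PCA triplets on common co-inertia axes.

    When ``truncate`` is set, each table is reconstructed from its
    retained principal components before the cross-covariance is formed
    (so only the variation kept by the separate PCAs is coupled);
    otherwise the full centered tables are used.  Row scores are the
    projections of each (possibly truncated) table on the unit-norm
    loading vectors of the common axes, so identical tables receive
    identical paired scores.  The RV coefficient is always computed on
    the full centered tables; a permutation p-value is attached when
    ``n_perm > 0``.
    """
    if A.n != B.n:
        raise ValueError("tables must share the same individuals")
    if A.row_ids is not None and B.row_ids is not None:
        if list(A.row_ids) != list(B.row_ids):
            bad = [x for x, y in zip(A.row_ids, B.row_ids) if x != y]
            raise ValueError(f"row IDs differ between tables: {bad[:5]}...")
    XA = A.truncated() if truncate else A.data
    XB = B.truncated() if truncate else B.data
    n = A.n
    C = XA.T @ XB / n
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k = min(XA.shape[1], XB.shape[1], n - 1)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    if XA.shape == XB.shape and np.array_equal(XA, XB):
        # self-coupling: the axes are exactly the PCA axes of the common
        # table; forcing V = U makes the paired scores coincide exactly
        V = U.copy()
    # orient each axis so the largest-|loading| coefficient of table A is
    # positive; apply the same flip to both sides
    for a in range(k):
        j = int(np.argmax(np.abs(U[:, a])))
        if U[j, a] < 0:
            U[:, a] = -U[:, a]
            V[:, a] = -V[:, a]
    per_axis = s ** 2
    total = float(np.sum(C ** 2))
    rv = rv_coefficient(A.data, B.data)
    rv_p = float("nan")
    if n_perm > 0:
        rv_p = rv_permutation_test(A.data, B.data, n_perm=n_perm, seed=seed)
    return CoIAResult(
        per_axis_coinertia=per_axis,
        total_coinertia=total,
        cum_coinertia_frac=np.cumsum(per_axis) / per_axis.sum(),
        rowscores_A=XA @ U,
        rowscores_B=XB @ V,
        loadings_A=U,
        loadings_B=V,
        rv=rv,
        rv_p=rv_p,
        n_perm=n_perm,
        truncated=truncate,
        individual_ids=A.row_ids if A.row_ids is not None else B.row_ids,
    )


@dataclasses.dataclass
class BootstrapRVNull:
    null_rv: np.ndarray
    observed_rv: float | None
    p_low: float | None          # P(null RV <= observed), one-sided "as low as"
    quantiles: dict[str, float]
    n_boot: int
    disjoint: bool
    seed: int | None


def bootstrap_rv_null(
    pool: GenotypeTable,
    subset_size: int,
    n_boot: int = 10000,
    disjoint: bool = True,
    seed: int | None = None,
    observed_rv: float | None = None,
    impute: str = "mode",
) -> BootstrapRVNull:
    """Null distribution of the RV between two random locus subsets of a
    non-candidate pool.

    Each iteration draws two ``subset_size``-locus subsets (sharing no
    locus when ``disjoint``), pushes both through the same
    impute-and-center path as the observed tables, and records their RV.
    The empirical p-value asks whether an observed RV is unusually LOW:
    p = (#{RV_null <= RV_obs} + 1)/(n_boot + 1).
    """
    p = pool.n_loci
    need = 2 * subset_size if disjoint else subset_size
    if p < need:
        raise ValueError(f"pool of {p} loci too small for subset size {subset_size}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    # imputation and centering are per-locus, so subsetting a single
    # imputed matrix equals imputing each subset separately
    X, _ = impute_and_center(pool, impute=impute)
    null = np.empty(n_boot)
    for it in range(n_boot):
        if disjoint:
            idx = rng.choice(p, size=2 * subset_size, replace=False)
            ia, ib = idx[:subset_size], idx[subset_size:]
        else:
            ia = rng.choice(p, size=subset_size, replace=False)
            ib = rng.choice(p, size=subset_size, replace=False)
        null[it] = rv_coefficient(X[:, ia], X[:, ib])
    qs = {f"q{q:g}": float(np.quantile(null, q)) for q in (0.0, 0.025, 0.5, 0.975, 1.0)}
    p_low = None
    if observed_rv is not None:
        p_low = (int(np.sum(null <= observed_rv)) + 1) / (n_boot + 1)
    return BootstrapRVNull(
        null_rv=null,
        observed_rv=observed_rv,
        p_low=p_low,
        quantiles=qs,
        n_boot=n_boot,
        disjoint=disjoint,
        seed=seed,
    )
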