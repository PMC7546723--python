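"""Redundancy analysis (RDA) of a genotype matrix on climate predictors,
permutation significance tests, and loading-based candidate-locus
detection.

RDA is the PCA of the fitted values of the multivariate linear regression
of the (column-centered) genotype matrix Y on the (standardized) predictor
matrix X.  Constrained eigenvalues measure predictor-explained variance;
locus loadings are the principal-axis coefficients of the fitted values
and candidate climate-selected loci are those whose loading on a
significant axis lies more than ``sd_mult`` standard deviations from the
mean loading of that axis.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from geacoia.data_io import GenotypeTable, filter_monomorphic, impute_and_center

__all__ = [
    "RDAResult",
    "CandidateSplit",
    "run_rda",
    "detect_outlier_loci",
    "assign_driving_variable",
    "split_candidates",
    "ezekiel_adjusted_r2",
]


@dataclasses.dataclass
class RDAResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    r2: float
    adj_r2: float
    individual_scores: np.ndarray      # n x axes, projections of Y on the constrained axes
    locus_loadings: np.ndarray         # p x axes, unit-norm principal-axis coefficients
    biplot_scores: np.ndarray          # q x axes, cor(predictor, constrained site score)
    pseudo_f: float
    global_p: float
    axis_f: np.ndarray
    axis_p: np.ndarray
    n_perm: int
    predictor_names: list[str] | None = None
    locus_ids: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return len(self.constrained_eigenvalues)

    def significant_axes(self, alpha: float = 0.05) -> list[int]:
        """0-based indices of axes whose sequential permutation p <= alpha."""
        return [i for i in range(self.n_axes) if self.axis_p[i] <= alpha]


@dataclasses.dataclass
class CandidateSplit:
    candidates: pd.DataFrame        # index locus_id; axis, loading, assigned_variable, assignment_r
    noncandidate_pool: list[str]
    noncandidate_sample: list[str]
    sample_seed: int


def ezekiel_adjusted_r2(r2: float, n: int, q: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - q - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _standardize(M: np.ndarray) -> np.ndarray:
    M = _center(np.asarray(M, dtype=float))
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return M / sd


def run_rda(
    Y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    predictor_names: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
) -> RDAResult:
    """Fit the RDA of Y (n individuals x p loci) on X (n x q predictors).

    Y is column-centered and X standardized internally (the intercept is
    absorbed by centering).  The global test permutes rows of X and
    compares pseudo-F = (SS_fit/q)/(SS_res/(n-q-1)); per-axis tests are
    sequential, conditioning on the previous constrained axes and
    permuting the reduced-model residuals.  Permutation p-values use the
    (exceedances + 1)/(n_perm + 1) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = _center(np.asarray(Y, dtype=float))
    X = _standardize(X)
    n, p = Y.shape
    if X.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    q = X.shape[1]
    if n <= q + 1:
        raise ValueError("need n > q + 1 individuals")
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("rank-deficient predictor matrix; run the VIF screen first")

    rng = np.random.default_rng(seed)
    Qx, _ = np.linalg.qr(X)
    Yhat = Qx @ (Qx.T @ Y)
    Yres = Y - Yhat

    ss_tot = float(np.sum(Y * Y))
    ss_fit = float(np.sum(Yhat * Yhat))
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot
    adj_r2 = ezekiel_adjusted_r2(r2, n, q)

    n_axes = min(q, p, n - 1)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    V = Vt[:n_axes].T                                   # p x axes loadings
    # deterministic sign: largest-|loading| coefficient positive per axis
    for a in range(n_axes):
        j = int(np.argmax(np.abs(V[:, a])))
        if V[j, a] < 0:
            V[:, a] = -V[:, a]
    eig_c = (s[:n_axes] ** 2) / (n - 1)
    sr = np.linalg.svd(Yres, compute_uv=False)
    eig_u = (sr[sr > 1e-10 * max(sr[0], 1.0)] ** 2) / (n - 1) if sr.size else sr

    scores = Y @ V
    lc_scores = Yhat @ V
    biplot = np.zeros((q, n_axes))
    for j in range(q):
        for a in range(n_axes):
            sd_a = lc_scores[:, a].std()
            biplot[j, a] = (
                np.corrcoef(X[:, j], lc_scores[:, a])[0, 1] if sd_a > 0 else 0.0
            )

    # global permutation test: permute rows of X
    f_obs = (ss_fit / q) / (ss_res / (n - q - 1))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssf = float(np.sum((Qx[perm].T @ Y) ** 2))
        f_perm = (ssf / q) / ((ss_tot - ssf) / (n - q - 1))
        if f_perm >= f_obs:
            exceed += 1
    global_p = (exceed + 1) / (n_perm + 1)

    # sequential axis tests
    axis_f = np.empty(n_axes)
    axis_p = np.empty(n_axes)
    ms_res = ss_res / (n - q - 1)
    for i in range(n_axes):
        axis_f[i] = eig_c[i] * (n - 1) / ms_res
        if i == 0:
            Yc, Xc = Y, X
        else:
            Z = lc_scores[:, :i]
            Qz, _ = np.linalg.qr(Z)
            Yc = Y - Qz @ (Qz.T @ Y)
            Xc = X - Qz @ (Qz.T @ X)
        Qc, Rc = np.linalg.qr(Xc)
        keep = np.abs(np.diag(Rc)) > 1e-10
        Qc = Qc[:, keep]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            M = Qc.T @ Yc[perm]
            lam1 = (np.linalg.svd(M, compute_uv=False)[0] ** 2) / (n - 1)
            ssf_p = float(np.sum(M * M))
            msr_p = (ss_tot - ss_fit) / (n - q - 1)  # residual MS of the full model
            f_perm = lam1 * (n - 1) / msr_p
            if f_perm >= axis_f[i]:
                exceed += 1
        axis_p[i] = (exceed + 1) / (n_perm + 1)

    return RDAResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_u,
        r2=r2,
        adj_r2=adj_r2,
        individual_scores=scores,
        locus_loadings=V,
        biplot_scores=biplot,
        pseudo_f=f_obs,
        global_p=global_p,
        axis_f=axis_f,
        axis_p=axis_p,
        n_perm=n_perm,
        predictor_names=list(predictor_names) if predictor_names is not None else None,
        locus_ids=np.asarray(locus_ids, dtype=object) if locus_ids is not None else None,
    )


def detect_outlier_loci(
    res: RDAResult,
    axes: Sequence[int] | None = None,
    sd_mult: float = 2.5,
) -> pd.DataFrame:
    """Flag loci whose loading on any listed axis lies more than
    ``sd_mult`` SD from the mean loading of that axis.

    ``axes`` are 0-based indices (default: all significant axes at 0.05).
    A locus flagged on several axes is attributed to the first axis in
    eigenvalue order (union semantics, no double counting).  Returns a
    frame indexed by locus with columns ``axis`` and ``loading``.
    """
    if axes is None:
        axes = res.significant_axes()
    axes = sorted(axes)
    if any(a < 0 or a >= res.n_axes for a in axes):
        raise ValueError("axis index out of range")
    p = res.locus_loadings.shape[0]
    if p < 2:
        raise ValueError("need at least 2 loci")
    ids = res.locus_ids if res.locus_ids is not None else np.arange(p).astype(object)
    flagged: dict[object, tuple[int, float]] = {}
    for a in axes:
        load = res.locus_loadings[:, a]
        sd = load.std(ddof=1)
        if sd == 0:
            warnings.warn(f"zero loading dispersion on axis {a}; no outliers flagged")
            continue
        out = np.abs(load - load.mean()) > sd_mult * sd
        for j in np.where(out)[0]:
            flagged.setdefault(ids[j], (a, float(load[j])))
    rows = [{"locus_id": l, "axis": ax, "loading": ld} for l, (ax, ld) in flagged.items()]
    df = pd.DataFrame(rows, columns=["locus_id", "axis", "loading"])
    return df.set_index("locus_id")


def assign_driving_variable(
    g: GenotypeTable,
    candidates: Sequence[str],
    climate_ind: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each candidate locus the climate variable its (imputed)
    dosages correlate most strongly with, in absolute Pearson r.

    ``climate_ind`` is an individuals x variables frame aligned to the
    genotype table rows (site-level climate expanded to individuals).
    Ties go to the lexicographically first variable name.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    sub = g.subset_loci(list(candidates))
    X, _ = impute_and_center(sub, impute="mode")
    variables = sorted(climate_ind.columns)
    C = climate_ind[variables].to_numpy(dtype=float)
    rows = []
    for j, locus in enumerate(candidates):
        x = X[:, j]
        if x.std() == 0:
            raise ValueError(f"zero-variance locus after imputation: {locus}")
        rs = np.array([np.corrcoef(x, C[:, v])[0, 1] for v in range(C.shape[1])])
        best = int(np.argmax(np.abs(rs)))
        rows.append({"locus_id": locus, "variable": variables[best], "r": float(rs[best])})
    return pd.DataFrame(rows).set_index("locus_id")


def split_candidates(
    g: GenotypeTable,
    candidates: Sequence[str],
    known_outliers: Sequence[str] = (),
    seed: int = 0,
) -> CandidateSplit:
    """Build the non-candidate pool and draw a size-matched random
    non-candidate sample.

    The pool excludes the candidates, any externally supplied outlier
    list, and monomorphic loci.  The sample is drawn uniformly without
    replacement with the recorded seed and has exactly as many loci as
    there are candidates.
    """
    _, monomorphic = filter_monomorphic(g)
    excluded = set(candidates) | set(known_outliers) | set(monomorphic)
    pool = [str(l) for l in g.locus_ids if str(l) not in excluded]
    k = len(candidates)
    if len(pool) < k:
        raise ValueError(
            f"non-candidate pool ({len(pool)}) smaller than candidate set ({k})")
    rng = np.random.default_rng(seed)
    sample = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    cand_df = pd.DataFrame(index=pd.Index(list(candidates), name="locus_id"))
    return CandidateSplit(
        candidates=cand_df,
        noncandidate_pool=pool,
        noncandidate_sample=sample,
        sample_seed=seed,
    )
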