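"""Predictor-set reduction: clustering of variables around latent
components (CLV) and an iterative variance-inflation-factor screen.

CLV groups standardized variables into clusters, each summarized by its
first principal component (the latent component); the quality of a
partition is the sum over clusters of the squared correlations between
member variables and their latent, which for standardized variables
equals the sum of leading eigenvalues of the within-cluster correlation
matrices.  The directional (sign-free, squared-correlation) variant is
used throughout, since climate variables have arbitrary sign
orientations.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from geacoia.data_io import ClimateTable

__all__ = ["CLVResult", "clv_cluster", "clv_criterion", "vif_screen"]


@dataclasses.dataclass
class CLVResult:
    k: int
    assignment: dict[str, int]          # variable -> cluster index (0..k-1)
    latent_scores: pd.DataFrame         # sites x k, columns "latent0"..
    criterion: float                    # criterion of the returned partition
    criterion_path: pd.Series           # index k (n_vars..1), criterion at the hierarchical cut
    representatives: dict[int, str]     # cluster -> best-correlated member variable

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(self.k)}
        for v, c in self.assignment.items():
            out[c].append(v)
        return out


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant variables cannot be clustered: {bad}")
    return (df - df.mean()) / sd


def _cluster_eig(Z: np.ndarray) -> tuple[float, np.ndarray]:
    """Leading eigenvalue and latent scores (PC1) of a block of
    standardized variables.  For a singleton the latent is the variable
    itself and the eigenvalue is 1."""
    if Z.shape[1] == 1:
        return 1.0, Z[:, 0].copy()
    R = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(R)
    lead = V[:, -1]
    scores = Z @ lead
    return float(w[-1]), scores


def clv_criterion(climate_df: pd.DataFrame, partition: list[list[str]]) -> float:
    """Sum over clusters of the leading correlation-matrix eigenvalue,
    i.e. sum of cor^2 between members and their first principal
    component.  Used both by the clustering and as an independent
    evaluation of candidate partitions."""
    Z = _standardize(climate_df)
    return sum(_cluster_eig(Z[c].to_numpy())[0] for c in partition)


def clv_cluster(
    climate: ClimateTable | pd.DataFrame,
    variables: list[str] | None = None,
    k: int | str = "auto",
    drop_fraction: float = 0.10,
    max_iter: int = 100,
) -> CLVResult:
    """Hierarchical CLV agglomeration followed by k-means-style
    consolidation.

    Starting from singletons, the pair of clusters whose merge loses the
    least criterion is merged at each step; the criterion value at every
    cut is recorded.  ``k='auto'`` keeps the largest k whose next merge
    would drop the criterion by more than ``drop_fraction`` of the total
    criterion (the number of variables, since standardized variables each
    carry unit variance).  Consolidation then reassigns variables to the
    latent they correlate best with until stable; it can only increase
    the criterion.
    """
    df = climate.df if isinstance(climate, ClimateTable) else climate
    if variables is None:
        variables = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if len(variables) < 2:
        raise ValueError("need at least 2 variables to cluster")
    Zdf = _standardize(df[variables])
    Z = Zdf.to_numpy()
    n_vars = len(variables)
    if isinstance(k, int) and (k < 1 or k > n_vars):
        raise ValueError(f"k must lie in [1, {n_vars}]")
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 sites")

    # hierarchical agglomeration
    clusters: list[list[int]] = [[j] for j in range(n_vars)]
    crits: dict[int, float] = {c: 1.0 for c in range(n_vars)}
    path: dict[int, float] = {n_vars: float(n_vars)}
    cuts: dict[int, list[list[int]]] = {n_vars: [list(c) for c in clusters]}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[a] + clusters[b]
            lam, _ = _cluster_eig(Z[:, merged])
            delta = lam - crits[a] - crits[b]
            if best is None or delta > best[0]:
                best = (delta, a, b, lam)
        _, a, b, lam = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        crits = {i: _cluster_eig(Z[:, c])[0] for i, c in enumerate(clusters)}
        kk = len(clusters)
        path[kk] = float(sum(crits.values()))
        cuts[kk] = [list(c) for c in clusters]

    if k == "auto":
        chosen = 1
        for kk in range(n_vars, 1, -1):
            if path[kk] - path[kk - 1] > drop_fraction * n_vars:
                chosen = kk
                break
    else:
        chosen = int(k)

    part = [list(c) for c in cuts[chosen]]

    # consolidation: reassign to best-correlated latent until stable
    def latents(partition: list[list[int]]) -> np.ndarray:
        return np.column_stack([_cluster_eig(Z[:, c])[1] for c in partition])

    crit = sum(_cluster_eig(Z[:, c])[0] for c in part)
    for _ in range(max_iter):
        L = latents(part)
        Ln = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
        r2 = (Zdf.to_numpy().T @ Ln / (Z.shape[0] - 1)) ** 2  # vars x k squared cor
        new_assign = np.argmax(r2, axis=1)
        new_part = [[j for j in range(n_vars) if new_assign[j] == c] for c in range(chosen)]
        if any(len(c) == 0 for c in new_part):
            break  # a cluster would empty; keep the current partition
        new_crit = sum(_cluster_eig(Z[:, c])[0] for c in new_part)
        if new_crit <= crit + 1e-12:
            break
        part, crit = new_part, new_crit

    # final latents, representatives, sign convention: latent oriented to
    # correlate positively with its representative
    assignment: dict[str, int] = {}
    reps: dict[int, str] = {}
    lat_cols = {}
    for c, members in enumerate(part):
        lam, scores = _cluster_eig(Z[:, members])
        sn = (scores - scores.mean()) / scores.std(ddof=1)
        r = np.array([np.corrcoef(Z[:, j], sn)[0, 1] for j in members])
        rep_j = members[int(np.argmax(r ** 2))]
        if r[int(np.argmax(r ** 2))] < 0:
            scores = -scores
        reps[c] = variables[rep_j]
        lat_cols[f"latent{c}"] = scores
        for j in members:
            assignment[variables[j]] = c

    return CLVResult(
        k=chosen,
        assignment=assignment,
        latent_scores=pd.DataFrame(lat_cols, index=df.index),
        criterion=float(crit),
        criterion_path=pd.Series(path).sort_index(ascending=False),
        representatives=reps,
    )


def vif_screen(
    climate: ClimateTable | pd.DataFrame,
    variables: list[str] | None = None,
    max_vif: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the largest-VIF variable until all VIFs <= max_vif.

    VIF_j = 1/(1 - R^2_j) from the OLS regression (with intercept) of
    variable j on all other variables.  Perfectly collinear variables get
    an infinite VIF and are dropped first, with a warning rather than an
    exception.  Returns the kept variables and a trace table with one row
    per (iteration, variable).
    """
    df = climate.df if isinstance(climate, ClimateTable) else climate
    if variables is None:
        variables = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    if df.shape[0] <= len(variables):
        raise ValueError("need more sites than variables for the VIF screen")
    kept = list(variables)
    rows = []
    iteration = 0
    while True:
        X = df[kept].to_numpy(dtype=float)
        vifs = {}
        for j, v in enumerate(kept):
            y = X[:, j]
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(len(y)), others])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ coef) ** 2))
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - rss / tss if tss > 0 else 1.0
            vifs[v] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda v: vifs[v])
        done = vifs[worst] <= max_vif or len(kept) == 1
        for v in kept:
            rows.append({"iteration": iteration, "variable": v, "vif": vifs[v],
                         "dropped": (not done and v == worst)})
        if done:
            break
        if np.isinf(vifs[worst]):
            warnings.warn(f"perfectly collinear variable dropped: {worst}")
        kept.remove(worst)
        iteration += 1
    return kept, pd.DataFrame(rows)
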