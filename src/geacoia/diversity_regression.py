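"""Population-level explanation of genomic divergence.

Builds per-site summaries (mean divergence, expected heterozygosity of the
candidate and non-candidate locus sets, climate values), selects the best
linear model of mean divergence by exhaustive subset search under AICc
(climate terms may enter linearly and quadratically, quadratic only with
its linear term), partitions the explained variance into unique and shared
adjusted-R^2 fractions of predictor blocks, and checks the per-site sample
size as a potential confounder.

Expected heterozygosity uses the plug-in estimator He = 2 p (1 - p) per
biallelic locus, averaged over loci with at least ``min_n`` genotyped
individuals in the population; an optional small-sample factor
2n/(2n - 1) is available.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from geacoia.data_io import ClimateTable, GenotypeTable, SampleFrame

__all__ = [
    "RegressionReport",
    "expected_heterozygosity",
    "he_correlation",
    "population_summary",
    "best_subset_aicc",
    "variation_partition",
    "confound_check",
    "aicc_ols",
]


def expected_heterozygosity(
    g: GenotypeTable,
    samples: SampleFrame,
    locus_set: Sequence[str],
    min_n: int = 4,
    unbiased: bool = False,
) -> pd.Series:
    """Per-site expected heterozygosity averaged over a locus set.

    For each site and locus with >= ``min_n`` genotyped individuals the
    allele frequency p is estimated from dosages and He = 2p(1-p)
    (optionally multiplied by 2n/(2n-1)); the site value is the mean over
    qualifying loci.  Loci failing the ``min_n`` rule are excluded for
    that site only; a site where no locus qualifies gets NaN with a
    warning.
    """
    if len(locus_set) == 0:
        raise ValueError("empty locus set")
    sub = g.subset_loci(list(locus_set))
    sites = samples.site_of(sub.individual_ids)
    out = {}
    for site in pd.unique(sites):
        rows = np.where(sites == site)[0]
        dos = sub.dosage[rows].astype(float)
        miss = sub.missing[rows]
        n_obs = (~miss).sum(axis=0)
        ok = n_obs >= min_n
        if not ok.any():
            warnings.warn(f"no locus with >= {min_n} genotyped individuals at {site}")
            out[site] = float("nan")
            continue
        s = np.where(miss, 0.0, dos).sum(axis=0)[ok]
        n = n_obs[ok]
        p = s / (2.0 * n)
        he = 2.0 * p * (1.0 - p)
        if unbiased:
            he = he * (2.0 * n) / (2.0 * n - 1.0)
        out[site] = float(he.mean())
    return pd.Series(out, name="He").sort_index()


def he_correlation(he_a: pd.Series, he_b: pd.Series) -> dict:
    """Pearson correlation (with two-sided t-test p) between two per-site
    He vectors, matched on site ID."""
    joined = pd.concat([he_a, he_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired sites")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an He vector")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(joined))}


def population_summary(
    divergence_df: pd.DataFrame,
    he_noncand: pd.Series,
    he_cand: pd.Series,
    climate: ClimateTable,
    climate_vars: Sequence[str] = ("BIO01", "BIO12"),
) -> pd.DataFrame:
    """Assemble the per-site table feeding the regression stage."""
    g = divergence_df.groupby("site_id")
    out = g.agg(mean_divergence=("divergence", "mean"),
                n_individuals=("divergence", "size"))
    out["He_noncandidate"] = he_noncand
    out["He_candidate"] = he_cand
    for v in climate_vars:
        out[v] = climate.df[v]
    if out.isna().any().any():
        bad = list(out.columns[out.isna().any()])
        raise ValueError(f"incomplete population summary columns: {bad}")
    return out


def aicc_ols(y: np.ndarray, X: np.ndarray | None) -> tuple[float, float]:
    """(AICc, RSS) of the least-squares Gaussian fit of y on X plus an
    intercept.  k counts the regression coefficients (incl. intercept)
    plus one for the error variance:
    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)."""
    n = len(y)
    A = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    k = A.shape[1] + 1
    if n - k - 1 <= 0:
        return float("inf"), rss
    aicc = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return float(aicc), rss


@dataclasses.dataclass
class RegressionReport:
    selected_terms: list[str]
    coefficients: pd.DataFrame      # term -> coef (standardized scale), coef_raw
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    p: float
    aicc_table: pd.DataFrame
    response: str


def _design(summary: pd.DataFrame, terms: Sequence[str],
            standardize: bool = True) -> np.ndarray | None:
    """Build the model matrix for a term list; quadratic terms are
    written ``I(var^2)`` and are squares of the standardized variable."""
    if not terms:
        return None
    cols = []
    for t in terms:
        if t.startswith("I(") and t.endswith("^2)"):
            v = t[2:-3]
            x = summary[v].to_numpy(dtype=float)
            if standardize:
                x = (x - x.mean()) / x.std(ddof=1)
            cols.append(x ** 2)
        else:
            x = summary[t].to_numpy(dtype=float)
            if standardize:
                x = (x - x.mean()) / x.std(ddof=1)
            cols.append(x)
    return np.column_stack(cols)


def enumerate_models(climate_vars: Sequence[str], he_terms: Sequence[str]) -> list[list[str]]:
    """All term subsets obeying the quadratic hierarchy: each climate
    variable enters not at all, linearly, or linearly + quadratically;
    each He term is in or out."""
    per_var = [[[], [v], [v, f"I({v}^2)"]] for v in climate_vars]
    per_he = [[[], [h]] for h in he_terms]
    models = []
    for combo in itertools.product(*(per_var + per_he)):
        terms = [t for part in combo for t in part]
        models.append(terms)
    return models


def best_subset_aicc(
    summary: pd.DataFrame,
    climate_vars: Sequence[str] = ("BIO01", "BIO12"),
    he_terms: Sequence[str] = ("He_noncandidate", "He_candidate"),
    response: str = "mean_divergence",
) -> RegressionReport:
    """Exhaustive subset selection of the divergence model under AICc.

    Predictors are standardized before the search (AICc comparisons are
    invariant to affine predictor rescaling; standardization just keeps
    the quadratic terms well conditioned).  Models whose k exceeds the
    sample size are skipped with a warning.  Coefficients of the winning
    model are reported on both the standardized and the raw scale.
    """
    y = summary[response].to_numpy(dtype=float)
    n = len(y)
    rows = []
    best: tuple[float, list[str]] | None = None
    for terms in enumerate_models(climate_vars, he_terms):
        X = _design(summary, terms)
        k = (0 if X is None else X.shape[1]) + 2
        if n - k - 1 <= 0:
            warnings.warn(f"model with {k - 2} terms skipped: too few sites")
            continue
        aicc, rss = aicc_ols(y, X)
        rows.append({"terms": " + ".join(terms) if terms else "(intercept)",
                     "n_terms": len(terms), "aicc": aicc, "rss": rss})
        if best is None or aicc < best[0] or (aicc == best[0] and len(terms) < len(best[1])):
            best = (aicc, terms)
    if best is None:
        raise ValueError("no candidate model is estimable at this sample size")
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()

    terms = best[1]
    Xs = _design(summary, terms, standardize=True)
    Xr = _design(summary, terms, standardize=False)
    import statsmodels.api as sm

    if Xs is None:
        fit = sm.OLS(y, np.ones((n, 1))).fit()
        coeffs = pd.DataFrame({"coef": fit.params, "coef_raw": fit.params},
                              index=["intercept"])
        adj_r2, f_stat, p, dfree = 0.0, float("nan"), float("nan"), (0, n - 1)
    else:
        fit = sm.OLS(y, sm.add_constant(Xs)).fit()
        fit_raw = sm.OLS(y, sm.add_constant(Xr)).fit()
        names = ["intercept"] + list(terms)
        coeffs = pd.DataFrame({"coef": fit.params, "coef_raw": fit_raw.params},
                              index=names)
        adj_r2 = float(fit.rsquared_adj)
        f_stat = float(fit.fvalue)
        p = float(fit.f_pvalue)
        dfree = (int(fit.df_model), int(fit.df_resid))
    return RegressionReport(
        selected_terms=list(terms),
        coefficients=coeffs,
        adj_r2=adj_r2,
        f_stat=f_stat,
        df=dfree,
        p=p,
        aicc_table=table,
        response=response,
    )


def _adj_r2(summary: pd.DataFrame, terms: Sequence[str], response: str) -> float:
    y = summary[response].to_numpy(dtype=float)
    X = _design(summary, terms)
    n = len(y)
    A = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    q = A.shape[1] - 1
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def variation_partition(
    summary: pd.DataFrame,
    block_a: Sequence[str],
    block_b: Sequence[str],
    response: str = "mean_divergence",
) -> dict:
    """Two-block variation partitioning on adjusted R^2.

    [a] = unique fraction of block A, [c] = unique fraction of block B,
    [b] = shared fraction (may be negative under adjustment), and
    unexplained = 1 - adjR^2(A union B).  All adjusted R^2 use the
    Ezekiel formula.
    """
    if set(block_a) & set(block_b):
        raise ValueError("blocks must be disjoint")
    if not block_a or not block_b:
        raise ValueError("blocks must be non-empty")
    r_ab = _adj_r2(summary, list(block_a) + list(block_b), response)
    r_a = _adj_r2(summary, block_a, response)
    r_b = _adj_r2(summary, block_b, response)
    a = r_ab - r_b
    c = r_ab - r_a
    b = r_a + r_b - r_ab
    return {
        "unique_A": float(a),
        "shared": float(b),
        "unique_B": float(c),
        "unexplained": float(1.0 - r_ab),
        "adj_r2_full": float(r_ab),
        "adj_r2_A": float(r_a),
        "adj_r2_B": float(r_b),
    }


def confound_check(summary: pd.DataFrame, response: str = "mean_divergence",
                   alpha: float = 0.05) -> dict:
    """Regress mean divergence on the number of genotyped individuals per
    site; flags a significant slope as a potential sampling confound."""
    n_ind = summary["n_individuals"].to_numpy(dtype=float)
    y = summary[response].to_numpy(dtype=float)
    if np.all(n_ind == n_ind[0]):
        return {"skipped": True, "note": "constant sample size; check not applicable"}
    res = stats.linregress(n_ind, y)
    return {
        "skipped": False,
        "slope": float(res.slope),
        "p": float(res.pvalue),
        "r": float(res.rvalue),
        "flagged": bool(res.pvalue < alpha),
    }
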