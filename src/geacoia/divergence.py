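"""Per-individual genomic divergence between paired co-inertia scores and
its geographic structure.

The divergence statistic is the Euclidean distance, over the leading
co-inertia axes, between an individual's scores for the candidate-locus
table and for the non-candidate-locus table.  In the paired "arrow"
display of a CoIA this is simply the arrow length.  Geographic structure
is tested with a nested linear model (basin, then site within basin,
sequential sums of squares).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from geacoia.coia import CoIAResult
from geacoia.data_io import SampleFrame

__all__ = ["DivergenceTable", "individual_divergence", "geographic_anova"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class DivergenceTable:
    df: pd.DataFrame             # index individual_id; divergence [, site_id, basin_id]
    axes_used: int
    coinertia_fraction_covered: float

    def population_means(self) -> pd.DataFrame:
        """Per-site mean divergence and sample size."""
        if "site_id" not in self.df.columns:
            raise ValueError("site labels required; pass samples to individual_divergence")
        g = self.df.groupby("site_id")
        out = g.agg(mean_divergence=("divergence", "mean"),
                    n_individuals=("divergence", "size"),
                    basin_id=("basin_id", "first"))
        return out


def individual_divergence(
    res: CoIAResult,
    k_axes: int | None = None,
    coverage: float | None = None,
    samples: SampleFrame | None = None,
) -> DivergenceTable:
    """Euclidean distance between paired CoIA scores on the leading axes.

    Exactly one of ``k_axes`` (explicit axis count) or ``coverage``
    (cumulative co-inertia fraction; the smallest axis count reaching it
    is used) selects the axes; with neither, all axes are used.  If the
    coverage fraction is unattainable all axes are used with a warning.
    """
    if k_axes is not None and coverage is not None:
        raise ValueError("give either k_axes or coverage, not both")
    n_avail = res.n_axes
    if k_axes is not None:
        if not 1 <= k_axes <= n_avail:
            raise ValueError(f"k_axes must lie in [1, {n_avail}]")
        k = int(k_axes)
    elif coverage is not None:
        if not 0.0 < coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        reach = np.where(res.cum_coinertia_frac >= coverage - 1e-12)[0]
        if reach.size == 0:
            log.warning("coverage %.3f unattainable; using all %d axes", coverage, n_avail)
            k = n_avail
        else:
            k = int(reach[0] + 1)
    else:
        k = n_avail
    diff = res.rowscores_A[:, :k] - res.rowscores_B[:, :k]
    d = np.sqrt(np.sum(diff ** 2, axis=1))
    ids = (res.individual_ids if res.individual_ids is not None
           else np.arange(len(d)).astype(object))
    df = pd.DataFrame({"divergence": d}, index=pd.Index(ids, name="individual_id"))
    if samples is not None:
        df["site_id"] = samples.site_of(df.index)
        df["basin_id"] = samples.basin_of(df.index)
    covered = float(res.cum_coinertia_frac[k - 1])
    return DivergenceTable(df=df, axes_used=k, coinertia_fraction_covered=covered)


def geographic_anova(d: DivergenceTable | pd.DataFrame) -> dict:
    """Nested linear model: divergence ~ basin + site within basin.

    Sequential (Type I) sums of squares with basin entered first; both
    F statistics use the residual mean square.  Because sites are nested
    in basins, the sequential decomposition reduces to between-basin,
    between-site-within-basin and within-site sums of squares, computed
    here by explicit group-mean projections.  Returns the ANOVA terms
    plus degrees of freedom and p-values.
    """
    from scipy import stats

    df = d.df if isinstance(d, DivergenceTable) else d
    for col in ("divergence", "site_id", "basin_id"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    if df.groupby("site_id")["basin_id"].nunique().max() > 1:
        raise ValueError("a site spans multiple basins")
    if df["basin_id"].nunique() < 2:
        raise ValueError("need >= 2 basins")
    y = df["divergence"].to_numpy(dtype=float)
    n = len(y)
    n_basins = df["basin_id"].nunique()
    n_sites = df["site_id"].nunique()
    df_basin = n_basins - 1
    df_site = n_sites - n_basins
    df_resid = n - n_sites

    # RSS under nested group-mean models
    rss0 = float(np.sum((y - y.mean()) ** 2))
    within = lambda key: float(
        df.groupby(key)["divergence"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    rss_basin = within("basin_id")
    rss_site = within("site_id")
    ss_basin = rss0 - rss_basin
    ss_site = rss_basin - rss_site
    ss_resid = rss_site

    if df_resid <= 0 or np.isclose(rss0, 0.0):
        log.info("degenerate divergence ANOVA (zero variance or no residual df)")
        return {
            "F_basin": 0.0, "df_basin": df_basin, "p_basin": 1.0,
            "F_site_within_basin": 0.0, "df_site_within_basin": df_site,
            "p_site_within_basin": 1.0, "df_resid": df_resid, "table": None,
        }
    ms_resid = ss_resid / df_resid
    f_basin = (ss_basin / df_basin) / ms_resid if ms_resid > 0 else 0.0
    f_site = (ss_site / df_site) / ms_resid if (ms_resid > 0 and df_site > 0) else 0.0
    p_basin = float(stats.f.sf(f_basin, df_basin, df_resid))
    p_site = float(stats.f.sf(f_site, df_site, df_resid)) if df_site > 0 else float("nan")
    table = pd.DataFrame(
        {
            "df": [df_basin, df_site, df_resid],
            "sum_sq": [ss_basin, ss_site, ss_resid],
            "mean_sq": [ss_basin / df_basin,
                        ss_site / df_site if df_site > 0 else float("nan"),
                        ms_resid],
            "F": [f_basin, f_site, float("nan")],
            "p": [p_basin, p_site, float("nan")],
        },
        index=["basin", "site_within_basin", "residual"],
    )
    return {
        "F_basin": float(f_basin), "df_basin": df_basin, "p_basin": p_basin,
        "F_site_within_basin": float(f_site), "df_site_within_basin": df_site,
        "p_site_within_basin": p_site, "df_resid": df_resid, "table": table,
    }
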