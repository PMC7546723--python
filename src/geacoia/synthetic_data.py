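"""Synthetic genotype / metadata / climate generator with planted
climate-selected loci.

The generator emulates the sampling design the analysis pipeline assumes:
individuals nested in sites (wetlands) nested in basins along a latitudinal
gradient, genotyped at unlinked biallelic SNPs.  Neutral differentiation
follows a two-level Balding-Nichols (F-model) hierarchy: an ancestral
allele frequency p is drawn per locus, basin frequencies are
Beta(p(1-F)/F, (1-p)(1-F)/F) with F the basin-level differentiation, and
site frequencies are drawn the same way around their basin frequency with
the site-level F.  A minority of "selected" loci additionally track one
climate variable: their site frequency is shifted on the logit scale by
beta times the standardized site value of the driving variable.  Genotypes
are Binomial(2, p_site) and missing genotypes are planted independently.

Every simulated locus is described in a ground-truth table so downstream
detection stages can be scored for sensitivity and false-flag rate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from geacoia.data_io import (
    ClimateTable,
    GenotypeTable,
    SampleFrame,
    write_matrix012,
    write_vcf,
)

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "make_climate", "write_fixture"]

BIOCLIM_VARS = [f"BIO{i:02d}" for i in range(1, 20)]

# Fixed latitudinal slopes (in z-units of latitude) for the 11
# temperature-like variables BIO01-BIO11.  They share a common sign
# structure so the variables are strongly collinear, as real bioclim
# extractions are.
_TEMP_BASE = np.array([12.0, 14.0, 55.0, 450.0, 24.0, 0.5, 23.0, 14.0, 9.0, 17.0, 6.0])
_TEMP_SLOPE = np.array([-2.0, 0.8, 3.0, -40.0, -2.5, -1.8, -0.9, -2.2, -1.6, -2.1, -1.9])
# Relative scales for the 8 precipitation-like variables BIO12-BIO19,
# all proportional to the annual-precipitation gradient.
_PREC_SCALE = np.array([1.0, 0.18, 0.02, 0.9, 0.45, 0.01, 0.40, 0.05])


@dataclasses.dataclass
class SimConfig:
    """Parameters of the hierarchical genotype simulation.

    ``inds_per_site`` may be a fixed count or an inclusive (low, high)
    range from which per-site sample sizes are drawn uniformly; the
    default (4, 10) mirrors typical wetland collections.
    ``climate_effect_beta`` is the per-selected-locus slope on the logit
    of the site allele frequency per SD of the driving climate variable;
    a scalar applies to every selected locus, a sequence gives one slope
    per locus.
    """

    n_basins: int = 5
    sites_per_basin: int = 4
    inds_per_site: int | tuple[int, int] = (4, 10)
    n_neutral_loci: int = 1619
    n_selected_loci: int = 90
    fst_basin: float = 0.10
    fst_site: float = 0.05
    climate_effect_beta: float | Sequence[float] = 1.5
    driving_variable: str = "BIO12"
    climate_noise_sd: float = 0.25
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_basins", "sites_per_basin", "n_neutral_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_selected_loci < 0:
            raise ValueError("n_selected_loci must be >= 0")
        for name in ("fst_basin", "fst_site"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self._ind_range()
        if lo < 1:
            raise ValueError("every site needs at least one individual")
        if hi < lo:
            raise ValueError("inds_per_site range is empty")

    def _ind_range(self) -> tuple[int, int]:
        if isinstance(self.inds_per_site, (tuple, list)):
            lo, hi = self.inds_per_site
            return int(lo), int(hi)
        return int(self.inds_per_site), int(self.inds_per_site)

    def betas(self) -> np.ndarray:
        if np.isscalar(self.climate_effect_beta):
            return np.full(self.n_selected_loci, float(self.climate_effect_beta))
        b = np.asarray(self.climate_effect_beta, dtype=float)
        if b.shape != (self.n_selected_loci,):
            raise ValueError("climate_effect_beta length must equal n_selected_loci")
        return b


@dataclasses.dataclass
class SimTruth:
    """Ground truth per simulated locus: selection status, planted logit
    slope, driving climate variable and ancestral allele frequency."""

    df: pd.DataFrame  # index locus_id; is_selected, beta, driving_variable, ancestral_freq

    @property
    def selected_loci(self) -> list[str]:
        return list(self.df.index[self.df["is_selected"]])

    @property
    def neutral_loci(self) -> list[str]:
        return list(self.df.index[~self.df["is_selected"]])


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float,
                     size: tuple[int, ...]) -> np.ndarray:
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    out = rng.beta(a, b, size=size)
    # keep frequencies usable on the logit scale
    return np.clip(out, 1e-6, 1.0 - 1e-6)


def make_climate(latitudes: np.ndarray, longitudes: np.ndarray,
                 rng: np.random.Generator, noise_sd: float = 0.25) -> pd.DataFrame:
    """Bioclim-style site table: 19 variables linear in latitude plus
    Gaussian noise, with annual precipitation (BIO12) spanning an order
    of magnitude and increasing with latitude (toward the south pole a
    negative latitude grows in magnitude, so the gradient runs north to
    south in absolute terms)."""
    lat = np.asarray(latitudes, dtype=float)
    n = len(lat)
    lat_z = (lat - lat.mean()) / lat.std()
    cols: dict[str, np.ndarray] = {}
    for i in range(11):
        noise = rng.normal(0.0, noise_sd * abs(_TEMP_SLOPE[i]), n)
        cols[BIOCLIM_VARS[i]] = _TEMP_BASE[i] + _TEMP_SLOPE[i] * lat_z + noise
    # precipitation gradient: one order of magnitude across the extent
    lat01 = (lat - lat.min()) / (lat.max() - lat.min()) if n > 1 else np.zeros(n)
    precip = 80.0 * 10.0 ** lat01 * np.exp(rng.normal(0.0, noise_sd * 0.4, n))
    for i in range(8):
        extra = np.exp(rng.normal(0.0, noise_sd * 0.3, n))
        cols[BIOCLIM_VARS[11 + i]] = _PREC_SCALE[i] * precip * extra
    df = pd.DataFrame(cols)
    df.insert(0, "longitude", np.asarray(longitudes, dtype=float))
    df.insert(0, "latitude", lat)
    return df


def simulate_dataset(config: SimConfig) -> tuple[GenotypeTable, SampleFrame, ClimateTable, SimTruth]:
    """Simulate genotypes, sample metadata, site climate and ground truth.

    Fully reproducible: the same config (including seed) yields identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_basins * config.sites_per_basin
    basin_ids = np.repeat([f"basin{b + 1}" for b in range(config.n_basins)],
                          config.sites_per_basin)
    site_ids = np.array([f"site{s + 1:02d}" for s in range(n_sites)], dtype=object)

    # basins occupy contiguous latitudinal blocks over a ~5.5 degree extent
    lat_north, lat_south = -27.0, -32.5
    basin_centers = np.linspace(lat_north, lat_south, config.n_basins)
    site_lat = np.empty(n_sites)
    for s in range(n_sites):
        b = s // config.sites_per_basin
        site_lat[s] = basin_centers[b] + rng.normal(0.0, 0.25)
    site_lon = -70.3 + 0.12 * (site_lat - site_lat.mean()) + rng.normal(0.0, 0.15, n_sites)
    site_elev = 3500.0 + 120.0 * rng.normal(0.0, 1.0, n_sites)

    climate_df = make_climate(site_lat, site_lon, rng, config.climate_noise_sd)
    climate_df.index = pd.Index(site_ids, name="site_id")
    climate = ClimateTable(climate_df)
    if config.driving_variable not in climate_df.columns:
        raise ValueError(f"unknown driving variable: {config.driving_variable!r}")
    z_drive = climate_df[config.driving_variable].to_numpy()
    z_drive = (z_drive - z_drive.mean()) / z_drive.std()

    # per-site sample sizes and individual metadata
    lo, hi = config._ind_range()
    n_per_site = rng.integers(lo, hi + 1, size=n_sites)
    ind_ids, ind_site, ind_basin = [], [], []
    for s in range(n_sites):
        for k in range(n_per_site[s]):
            ind_ids.append(f"{site_ids[s]}_ind{k + 1}")
            ind_site.append(site_ids[s])
            ind_basin.append(basin_ids[s])
    n_ind = len(ind_ids)
    samples = SampleFrame(pd.DataFrame(
        {
            "site_id": ind_site,
            "basin_id": ind_basin,
            "latitude": site_lat[[list(site_ids).index(s) for s in ind_site]],
            "longitude": site_lon[[list(site_ids).index(s) for s in ind_site]],
            "elevation": site_elev[[list(site_ids).index(s) for s in ind_site]],
        },
        index=pd.Index(ind_ids, name="individual_id"),
    ))

    # locus bookkeeping: selected loci at random positions
    n_loci = config.n_neutral_loci + config.n_selected_loci
    locus_ids = np.array([f"snp{j + 1:05d}" for j in range(n_loci)], dtype=object)
    sel_idx = rng.choice(n_loci, size=config.n_selected_loci, replace=False)
    is_selected = np.zeros(n_loci, dtype=bool)
    is_selected[sel_idx] = True
    beta = np.zeros(n_loci)
    beta[sel_idx] = config.betas()

    # hierarchical allele frequencies
    p_anc = rng.uniform(0.05, 0.95, n_loci)
    basin_rows = np.repeat(np.arange(config.n_basins), config.sites_per_basin)
    p_basin = _balding_nichols(rng, p_anc[None, :].repeat(config.n_basins, axis=0),
                               config.fst_basin, (config.n_basins, n_loci))
    p_site = _balding_nichols(rng, p_basin[basin_rows, :], config.fst_site,
                              (n_sites, n_loci))
    logit = np.log(p_site / (1.0 - p_site))
    logit[:, sel_idx] += z_drive[:, None] * beta[sel_idx][None, :]
    p_site = 1.0 / (1.0 + np.exp(-logit))

    site_of_ind = np.array([list(site_ids).index(s) for s in ind_site])
    dosage = rng.binomial(2, p_site[site_of_ind, :]).astype(np.int8)
    missing = rng.random((n_ind, n_loci)) < config.missing_rate
    # a fully-missing locus violates the container invariant; reveal one genotype
    all_miss = missing.all(axis=0)
    if all_miss.any():
        missing[0, all_miss] = False
    genotypes = GenotypeTable(dosage, missing, locus_ids, np.array(ind_ids, dtype=object))

    truth = SimTruth(pd.DataFrame(
        {
            "is_selected": is_selected,
            "beta": beta,
            "driving_variable": np.where(is_selected, config.driving_variable, ""),
            "ancestral_freq": p_anc,
        },
        index=pd.Index(locus_ids, name="locus_id"),
    ))
    return genotypes, samples, climate, truth


def write_fixture(dataset: tuple, out_dir: str | Path, force: bool = False) -> dict[str, Path]:
    """Write a simulated dataset as VCF + 012 matrix + metadata + climate
    + truth tables.  Refuses to write into an existing non-empty directory
    unless ``force`` is set."""
    genotypes, samples, climate, truth = dataset
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory not empty: {out} (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "matrix012": out / "genotypes012.tsv",
        "samples": out / "samples.tsv",
        "climate": out / "climate.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(genotypes, paths["vcf"])
    write_matrix012(genotypes, paths["matrix012"])
    samples.df.to_csv(paths["samples"], sep="\t")
    climate.df.to_csv(paths["climate"], sep="\t")
    truth.df.to_csv(paths["truth"], sep="\t")
    return paths
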