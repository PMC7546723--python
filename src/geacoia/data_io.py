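"""Readers, writers and validated in-memory containers for genotype,
sample-metadata and climate tables.

Genotypes are diploid biallelic SNPs coded as alternate-allele dosage
0/1/2 with an explicit missing mask.  Supported external formats are
VCF 4.2 (diploid GT fields, ``./.`` for missing) and a plain tab-delimited
012 matrix (header row of locus IDs, first column of individual IDs,
missing coded ``NA``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "SampleFrame",
    "ClimateTable",
    "read_genotypes",
    "read_matrix012",
    "read_vcf",
    "write_matrix012",
    "write_vcf",
    "read_samples",
    "read_climate",
    "filter_monomorphic",
    "impute_and_center",
    "climate_for_individuals",
]


@dataclasses.dataclass
class GenotypeTable:
    """Individuals x loci dosage matrix with missing mask.

    ``dosage`` holds alternate-allele counts in {0,1,2}; entries where
    ``missing`` is True are undefined (stored as 0 by convention).
    """

    dosage: np.ndarray
    missing: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, p = self.dosage.shape
        if self.missing.shape != (n, p):
            raise ValueError("missing mask shape does not match dosage matrix")
        if len(self.individual_ids) != n or len(self.locus_ids) != p:
            raise ValueError("ID lengths do not match matrix dimensions")
        for name, ids in (("individual", self.individual_ids), ("locus", self.locus_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicated {name} IDs")
        obs = self.dosage[~self.missing]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in {0,1,2}")
        all_missing = self.missing.all(axis=0)
        if all_missing.any():
            bad = list(self.locus_ids[all_missing])
            raise ValueError(f"loci with all genotypes missing: {bad}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        """Return a new table restricted to ``loci`` (order as given)."""
        index = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            cols = [index[l] for l in loci]
        except KeyError as exc:
            raise KeyError(f"unknown locus ID: {exc.args[0]}") from None
        return GenotypeTable(
            self.dosage[:, cols],
            self.missing[:, cols],
            np.asarray(list(loci), dtype=object),
            self.individual_ids.copy(),
        )

    def allele_freqs(self) -> np.ndarray:
        """Per-locus alternate-allele frequency from non-missing dosages."""
        d = np.where(self.missing, 0, self.dosage).astype(float)
        n_obs = (~self.missing).sum(axis=0)
        return d.sum(axis=0) / (2.0 * n_obs)


@dataclasses.dataclass
class SampleFrame:
    """Individual -> site -> basin hierarchy with coordinates.

    Wraps a DataFrame indexed by individual ID with columns
    ``site_id``, ``basin_id``, ``latitude``, ``longitude``, ``elevation``.
    """

    df: pd.DataFrame

    REQUIRED = ("site_id", "basin_id", "latitude", "longitude", "elevation")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"sample table missing columns: {missing_cols}")
        if self.df.index.duplicated().any():
            raise ValueError("duplicated individual IDs in sample table")
        # each site must map to exactly one basin
        nb = self.df.groupby("site_id")["basin_id"].nunique()
        bad = nb[nb > 1]
        if len(bad):
            raise ValueError(f"sites mapped to multiple basins: {list(bad.index)}")

    def site_of(self, individuals: Sequence[str]) -> np.ndarray:
        try:
            return self.df.loc[list(individuals), "site_id"].to_numpy()
        except KeyError:
            known = set(self.df.index)
            orphans = [i for i in individuals if i not in known]
            raise ValueError(f"individuals without metadata: {orphans}") from None

    def basin_of(self, individuals: Sequence[str]) -> np.ndarray:
        self.site_of(individuals)  # validates
        return self.df.loc[list(individuals), "basin_id"].to_numpy()

    @property
    def site_basin(self) -> pd.Series:
        """site_id -> basin_id mapping."""
        return self.df.groupby("site_id")["basin_id"].first()


@dataclasses.dataclass
class ClimateTable:
    """Site-level climate variables; one row per site, no missing values."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValueError("duplicated site IDs in climate table")
        if self.df.isna().any().any():
            bad = list(self.df.columns[self.df.isna().any()])
            raise ValueError(f"climate table has missing values in: {bad}")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.df.columns if pd.api.types.is_numeric_dtype(self.df[c])]


# ---------------------------------------------------------------------------
# genotype readers / writers


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read diploid biallelic genotypes from a VCF into dosage coding.

    Dosage counts the alternate allele: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing.  Multiallelic records and non-diploid GT fields are
    hard errors naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    dosage_rows: list[np.ndarray] = []
    missing_rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    for var in vcf:
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record not supported: {rid}")
        dos = np.empty(len(individuals), dtype=np.int8)
        miss = np.zeros(len(individuals), dtype=bool)
        for j, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(f"non-diploid genotype at {rid}, sample {individuals[j]}")
            if alleles[0] < 0 or alleles[1] < 0:
                miss[j] = True
                dos[j] = 0
            else:
                dos[j] = int(alleles[0] > 0) + int(alleles[1] > 0)
        locus_ids.append(rid)
        dosage_rows.append(dos)
        missing_rows.append(miss)
    vcf.close()
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus IDs in VCF")
    dosage = np.stack(dosage_rows, axis=1)
    missing = np.stack(missing_rows, axis=1)
    return GenotypeTable(dosage, missing, np.array(locus_ids, dtype=object),
                         np.array(individuals, dtype=object))


def read_matrix012(path: str | Path, sep: str = "\t") -> GenotypeTable:
    """Read a 012 dosage matrix (header of locus IDs, first column of
    individual IDs, missing = NA)."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    missing = df.isna().to_numpy()
    dosage = df.fillna(0).to_numpy().astype(np.int8)
    return GenotypeTable(dosage, missing,
                         np.array([str(c) for c in df.columns], dtype=object),
                         np.array([str(i) for i in df.index], dtype=object))


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeTable:
    """Dispatch to :func:`read_vcf` (``format='vcf'``) or
    :func:`read_matrix012` (``format='matrix012'``)."""
    if format == "vcf":
        return read_vcf(path)
    if format in ("matrix012", "012"):
        return read_matrix012(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_matrix012(g: GenotypeTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(g.dosage.astype(object), index=g.individual_ids, columns=g.locus_ids)
    df = df.mask(g.missing, other="NA")
    df.index.name = "individual_id"
    df.to_csv(path, sep=sep)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with synthetic positions (one per locus)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + [str(i) for i in g.individual_ids]) + "\n")
        for j, locus in enumerate(g.locus_ids):
            fields = ["1", str(j + 1), str(locus), "A", "T", ".", "PASS", ".", "GT"]
            for i in range(g.n_individuals):
                fields.append("./." if g.missing[i, j] else _GT_CODE[int(g.dosage[i, j])])
            fh.write("\t".join(fields) + "\n")


def read_samples(path: str | Path, sep: str = "\t") -> SampleFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df["site_id"] = df["site_id"].astype(str)
    df["basin_id"] = df["basin_id"].astype(str)
    return SampleFrame(df)


def read_climate(path: str | Path, sep: str = "\t") -> ClimateTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ClimateTable(df)


# ---------------------------------------------------------------------------
# preprocessing


def filter_monomorphic(g: GenotypeTable) -> tuple[GenotypeTable, list[str]]:
    """Remove loci whose non-missing dosages are all identical.

    Returns the filtered table and the list of removed locus IDs; the
    relative order of retained loci is preserved.
    """
    keep = []
    removed = []
    for j in range(g.n_loci):
        obs = g.dosage[~g.missing[:, j], j]
        if obs.size and np.all(obs == obs[0]):
            removed.append(str(g.locus_ids[j]))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all loci are monomorphic")
    filtered = GenotypeTable(
        g.dosage[:, keep], g.missing[:, keep],
        g.locus_ids[keep], g.individual_ids.copy(),
    )
    return filtered, removed


def impute_and_center(
    g: GenotypeTable,
    impute: str = "mode",
    scale: bool = False,
) -> tuple[np.ndarray, dict]:
    """Impute missing dosages per locus, center columns, optionally scale.

    ``impute='mode'`` replaces missing values by the locus' most common
    observed genotype (ties broken toward the smaller dosage);
    ``impute='mean'`` by the locus mean dosage.  Returns the dense float
    matrix and a transform record ``{fill, mean, scale}`` sufficient to
    reproduce the output from the raw table.
    """
    X = g.dosage.astype(float).copy()
    fill = np.empty(g.n_loci)
    for j in range(g.n_loci):
        m = g.missing[:, j]
        obs = g.dosage[~m, j]
        if impute == "mode":
            counts = np.bincount(obs, minlength=3)
            fill[j] = int(np.argmax(counts))  # argmax takes the first (smaller) on ties
        elif impute == "mean":
            fill[j] = obs.mean()
        else:
            raise ValueError(f"unknown imputation mode: {impute!r}")
        X[m, j] = fill[j]
    means = X.mean(axis=0)
    X -= means
    sds = None
    if scale:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = list(g.locus_ids[sds == 0])
            raise ValueError(f"cannot scale zero-variance loci: {bad}")
        X /= sds
    transform = {"impute": impute, "fill": fill, "mean": means, "sd": sds}
    return X, transform


def climate_for_individuals(
    climate: ClimateTable, samples: SampleFrame, individuals: Sequence[str],
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Expand site-level climate to an individuals x variables frame,
    aligned to ``individuals``.  Errors on individuals without metadata
    or sites without climate."""
    sites = samples.site_of(individuals)
    vars_ = list(variables) if variables is not None else climate.variables
    missing_sites = sorted(set(sites) - set(climate.df.index))
    if missing_sites:
        raise ValueError(f"sites without climate data: {missing_sites}")
    out = climate.df.loc[sites, vars_].copy()
    out.index = pd.Index(individuals, name="individual_id")
    return out
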