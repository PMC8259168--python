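"""Core in-memory containers shared by every analysis stage.

Genotypes, feature tables and GWAS summary statistics are kept as thin
wrappers around :class:`pandas.DataFrame` so that every downstream stage can
use ordinary pandas/numpy idioms, while construction enforces the invariants
the pipeline relies on (unique ids, MAF bounds, positive standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FeatureMatrix",
    "SummaryStats",
    "PLATFORMS",
    "SUMMARY_COLUMNS",
]

PLATFORMS = ("BM", "GM", "UM", "cytokine", "cellcount", "other")

#: canonical GWAS summary-statistic column dialect
SUMMARY_COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]


def compute_maf(dosage: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per SNP from 0..2 dosages, ignoring missing."""
    af = dosage.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(af, 1.0 - af)
    return pd.Series(maf, index=dosage.columns, name="maf")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosage
        DataFrame indexed by sample id with one column per SNP; values in
        [0, 2], NaN for missing genotypes.
    snps
        DataFrame indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and ``maf``. ``maf`` is recomputed from the dosages
        on construction.
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosage.columns.equals(self.snps.index):
            self.snps = self.snps.loc[self.dosage.columns]
        if self.dosage.columns.has_duplicates:
            raise ValueError("duplicate SNP ids")
        if self.dosage.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.dosage.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("pos must be strictly positive (1-based)")
        self.snps = self.snps.copy()
        self.snps["maf"] = compute_maf(self.dosage)

    @property
    def samples(self) -> pd.Index:
        return self.dosage.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosage[ids], self.snps.loc[ids])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosage.loc[ids], self.snps)

    def imputed_dosage(self) -> pd.DataFrame:
        """Dosages with missing entries mean-imputed per SNP (analysis-time
        convenience; never persisted)."""
        return self.dosage.fillna(self.dosage.mean(axis=0))


@dataclass
class FeatureMatrix:
    """Samples x features matrix (metabolites, cytokines, cell counts...).

    ``platform`` tags the measurement family: BM (targeted NMR lipoprotein
    panel), GM (flow-injection TOF-MS), UM (untargeted NMR/GC-MS/LC-MS),
    cytokine, cellcount or other.
    """

    values: pd.DataFrame
    platform: str = "other"
    annotation: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[pd.Index(ids)], self.platform, self.annotation)


@dataclass
class SummaryStats:
    """Per-SNP GWAS effect table for a single trait.

    Columns follow the canonical dialect :data:`SUMMARY_COLUMNS`. ``beta`` is
    the effect of one copy of the effect allele ``ea``; ``eaf`` its frequency.
    For case-control traits beta is on the log-odds scale.
    """

    table: pd.DataFrame
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control" and self.case_fraction is None:
            raise ValueError("case_fraction required for case_control traits")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("se must be strictly positive")
        if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
            raise ValueError("eaf must lie strictly inside (0, 1)")
        if t["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary statistics")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp"])

    def zscores(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()
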