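"""Metabolite-QTL mapping: additive per-SNP linear scans with covariates,
per-platform Bonferroni thresholds, LD-based locus clumping and
per-metabolite genetic variance.

The scan residualizes features and dosages on the covariates once and then
runs per-pair simple regressions; by the Frisch-Waugh-Lovell theorem the
slope equals the full multiple-regression coefficient, and t/p are computed
at the full-model degrees of freedom n - k - 2 (k = covariate count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, FeatureMatrix
from .preprocess import residualize
from .varexp import adjusted_r2

log = logging.getLogger("metaboqtl")

__all__ = [
    "qtl_scan",
    "bonferroni_threshold",
    "clump_loci",
    "genetic_variance",
    "Locus",
]

GENOME_WIDE_ALPHA = 5e-8


def bonferroni_threshold(alpha_gw: float = GENOME_WIDE_ALPHA, m_features: int = 1) -> float:
    """Per-platform genome-wide threshold alpha_gw / m_features."""
    if m_features < 1:
        raise ValueError("m_features must be >= 1")
    return alpha_gw / m_features


def _residual_matrix(values: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    if covariates is None:
        return values - values.mean(axis=0)
    return residualize(FeatureMatrix(values, "other"), covariates).values


def qtl_scan(g: GenotypeMatrix, m: FeatureMatrix,
             covariates: pd.DataFrame | None = None,
             standardize_features: bool = True) -> pd.DataFrame:
    """Additive linear scan of every SNP against every feature.

    Features are expected log-transformed; they are z-scored (so betas are in
    feature-SD units per alt-allele dose) and, together with mean-imputed
    dosages, residualized on the covariates once. Samples are the
    intersection of genotypes, features and covariates. Returns a QTL record
    table (snp, feature, beta, se, t, p, n).
    """
    common = g.samples.intersection(m.samples)
    if covariates is not None:
        covariates = covariates.loc[covariates.index.intersection(common)]
        common = common.intersection(covariates.index)
    if len(common) < 10:
        raise ValueError(f"too few overlapping samples: {len(common)}")
    dosage = g.imputed_dosage().loc[common]
    feats = m.values.loc[common].astype(float)
    if feats.isna().any().any():
        feats = feats.fillna(feats.mean(axis=0))
        log.info("qtl_scan: mean-imputed missing feature entries")
    if standardize_features:
        sd = feats.std(axis=0, ddof=1)
        keep = sd[sd > 0].index
        feats = (feats[keep] - feats[keep].mean(axis=0)) / sd[keep]

    k = 0 if covariates is None else covariates.shape[1]
    n = len(common)
    df = n - k - 2
    if df < 1:
        raise ValueError("not enough degrees of freedom for the scan")
    Rg = _residual_matrix(dosage, covariates).to_numpy(dtype=float)
    Rf = _residual_matrix(feats, covariates).to_numpy(dtype=float)

    sxx = (Rg ** 2).sum(axis=0)
    ok = sxx > 1e-12
    if (~ok).any():
        log.info("qtl_scan: skipped %d SNPs constant after covariate adjustment",
                 int((~ok).sum()))
    sxy = Rg[:, ok].T @ Rf                    # S_ok x F
    syy = (Rf ** 2).sum(axis=0)
    beta = sxy / sxx[ok, None]
    rss = np.maximum(syy[None, :] - beta * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx[ok, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    snp_ids = dosage.columns.to_numpy()[ok]
    si, fi = np.meshgrid(np.arange(len(snp_ids)), np.arange(feats.shape[1]), indexing="ij")
    return pd.DataFrame({
        "snp": snp_ids[si.ravel()],
        "feature": feats.columns.to_numpy()[fi.ravel()],
        "beta": beta.ravel(),
        "se": se.ravel(),
        "t": t.ravel(),
        "p": p.ravel(),
        "n": n,
    })


@dataclass
class Locus:
    """A clumped genomic locus: lead SNP plus members in LD with it."""

    lead: str
    members: list
    features: list
    chrom: str
    span: tuple

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError("lead SNP must be a member of its locus")


def _ld_r2(dosage: pd.DataFrame, a: str, b: str) -> float:
    x, y = dosage[a].to_numpy(), dosage[b].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def clump_loci(records: pd.DataFrame, g: GenotypeMatrix,
               r2_threshold: float = 0.1, window_bp: float = 1e6) -> list[Locus]:
    """Greedy LD clumping of significant QTL records into loci.

    Repeatedly takes the unassigned SNP with the smallest p as lead and
    absorbs unassigned SNPs on the same chromosome within ``window_bp`` with
    dosage r^2 to the lead above ``r2_threshold``. ``records`` should be
    pre-filtered to a significance threshold by the caller.
    """
    missing = set(records["snp"]) - set(g.snp_ids)
    if missing:
        raise ValueError(f"records contain SNPs absent from genotypes: {sorted(missing)[:5]}")
    best = (records.sort_values(["p", "snp"]).groupby("snp", sort=False)
            .first().reset_index())
    feats_by_snp = records.groupby("snp")["feature"].apply(lambda s: sorted(set(s))).to_dict()
    dosage = g.imputed_dosage()
    unassigned = set(best["snp"])
    order = best.sort_values(["p", "snp"])["snp"].tolist()
    loci: list[Locus] = []
    for lead in order:
        if lead not in unassigned:
            continue
        lead_chrom = str(g.snps.loc[lead, "chrom"])
        lead_pos = int(g.snps.loc[lead, "pos"])
        members = [lead]
        for other in sorted(unassigned):
            if other == lead:
                continue
            if str(g.snps.loc[other, "chrom"]) != lead_chrom:
                continue
            if abs(int(g.snps.loc[other, "pos"]) - lead_pos) > window_bp:
                continue
            if _ld_r2(dosage, lead, other) > r2_threshold:
                members.append(other)
        unassigned -= set(members)
        feats = sorted({f for s in members for f in feats_by_snp.get(s, [])})
        positions = [int(g.snps.loc[s, "pos"]) for s in members]
        loci.append(Locus(lead, sorted(members), feats, lead_chrom,
                          (min(positions), max(positions))))
    return loci


def genetic_variance(feature: pd.Series, leads: list, g: GenotypeMatrix,
                     covariates: pd.DataFrame | None = None) -> float:
    """Adjusted R^2 of a metabolite on its independent lead SNPs.

    The feature is residualized on the covariates, then regressed on the
    lead-SNP dosages jointly; the (0-clamped) adjusted R^2 is the fraction of
    metabolite variance attributed to genetics.
    """
    if not leads:
        return 0.0
    common = g.samples.intersection(feature.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
    y = feature.loc[common].astype(float)
    ok = y.notna()
    y = y[ok]
    n = len(y)
    if len(leads) >= n - 2:
        raise ValueError(f"too many lead SNPs ({len(leads)}) for n={n}")
    yv = pd.DataFrame({"y": y})
    cov = covariates.loc[y.index] if covariates is not None else None
    y_res = _residual_matrix(yv, cov)["y"].to_numpy()
    X = g.imputed_dosage().loc[y.index, leads].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y_res, rcond=None)
    fitted = design @ beta
    ss_tot = ((y_res - y_res.mean()) ** 2).sum()
    ss_res = ((y_res - fitted) ** 2).sum()
    r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)) if ss_tot > 0 else 0.0
    return max(adjusted_r2(r2, n, len(leads)), 0.0)
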