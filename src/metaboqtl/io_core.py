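"""Readers, writers and variant QC.

Dialects supported:

* genotypes — VCF 4.x (GT or DS per sample; DS preferred) via :mod:`cyvcf2`,
  or a plain TSV of dosages with samples as rows and SNPs as columns plus a
  side-car ``<path>.snps.tsv`` carrying per-SNP metadata;
* feature tables — TSV, samples as rows, header row of feature ids;
* GWAS summary statistics — TSV with the canonical columns
  ``snp chrom pos ea oa eaf beta se p n``;
* annotations — BED (0-based half-open, converted to 1-based inclusive on
  ingest) with a class label in the 4th column.

All coordinates inside the package are 1-based (VCF convention). Strand is
assumed forward throughout; palindromic ambiguity is handled only by the MR
harmonization policy.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, FeatureMatrix, SummaryStats, SUMMARY_COLUMNS

log = logging.getLogger("metaboqtl")

__all__ = [
    "read_genotype_matrix",
    "write_genotype_tsv",
    "write_genotype_vcf",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_bed_annotation",
    "filter_variants",
    "hwe_exact_test",
]


# ---------------------------------------------------------------------------
# genotypes


def read_genotype_matrix(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from VCF (GT/DS) or dosage TSV.

    VCF handling: biallelic SNPs only — multi-allelic records are skipped
    (not split) and the skip count logged; DS is used when present, else GT
    allele counts; missing GT becomes NaN and is excluded from MAF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan, gt.clip(min=0).sum(axis=1)).astype(float)
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        cols.append(d)
        meta.append((snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
    if n_multi:
        log.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not meta:
        raise ValueError(f"no biallelic records in {path}")
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "ref", "alt"]).set_index("snp")
    dosage = pd.DataFrame(np.column_stack(cols), index=pd.Index(samples, name="sample"),
                          columns=snps.index)
    return GenotypeMatrix(dosage, snps)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    dosage = pd.read_csv(path, sep="\t", index_col=0)
    dosage.index.name = "sample"
    dosage.columns.name = "snp"
    side = path.with_suffix(path.suffix + ".snps.tsv")
    if side.exists():
        snps = pd.read_csv(side, sep="\t", index_col=0, dtype={"chrom": str})
    else:
        snps = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, dosage.shape[1] + 1), "ref": "A", "alt": "G"},
            index=dosage.columns,
        )
    return GenotypeMatrix(dosage, snps)


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    g.dosage.to_csv(path, sep="\t")
    g.snps.to_csv(path.with_suffix(path.suffix + ".snps.tsv"), sep="\t")


def write_genotype_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write hard genotypes as a minimal VCF 4.2 with GT and DS fields."""
    path = Path(path)
    snps = g.snps.sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in snps["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.samples)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp_id, row in snps.iterrows():
            d = g.dosage[snp_id]
            fields = []
            for v in d:
                if pd.isna(v):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(v))]}:{v:g}")
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT:DS\t" + "\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# feature tables


def read_feature_matrix(path: str | Path, platform: str = "other") -> FeatureMatrix:
    values = pd.read_csv(Path(path), sep="\t", index_col=0)
    values.index.name = "sample"
    return FeatureMatrix(values, platform)


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    m.values.to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# summary statistics


def read_summary_stats(path: str | Path, trait_type: str = "quantitative",
                       case_fraction: float | None = None,
                       column_map: dict[str, str] | None = None) -> SummaryStats:
    """Read a GWAS summary TSV, validate rows, and warn on beta/se vs p
    inconsistencies.

    Rows with se <= 0 or eaf outside (0,1) are dropped with a row-level
    report. Allele columns are upper-cased. ``column_map`` renames foreign
    dialects onto the canonical columns.
    """
    t = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    if column_map:
        t = t.rename(columns=column_map)
    missing = [c for c in SUMMARY_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"summary statistics file missing required column(s): {missing}")
    t["ea"] = t["ea"].astype(str).str.upper()
    t["oa"] = t["oa"].astype(str).str.upper()
    bad = (t["se"] <= 0) | (t["eaf"] <= 0) | (t["eaf"] >= 1)
    if bad.any():
        for i in t.index[bad]:
            log.warning("rejected summary row %d (snp=%s): se=%s eaf=%s",
                        i, t.loc[i, "snp"], t.loc[i, "se"], t.loc[i, "eaf"])
        t = t[~bad]
    z = np.abs(t["beta"] / t["se"])
    p_implied = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(p_implied - t["p"]) / np.maximum(t["p"], 1e-300)
    n_off = int(((rel > 0.10) & (p_implied > 1e-280)).sum())
    if n_off:
        log.warning("%d rows in %s have p inconsistent with beta/se (>10%% relative)",
                    n_off, path)
    return SummaryStats(t.reset_index(drop=True), trait_type, case_fraction)


def write_summary_stats(s: SummaryStats, path: str | Path) -> None:
    s.table[SUMMARY_COLUMNS].to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


def read_bed_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED intervals with a class/gene label; 0-based half-open input is
    converted to 1-based inclusive."""
    t = pd.read_csv(Path(path), sep="\t", header=None,
                    names=["chrom", "start", "end", "label"],
                    dtype={"chrom": str})
    out = pd.DataFrame({
        "chrom": t["chrom"],
        "start": t["start"].astype(int) + 1,   # 1-based inclusive
        "end": t["end"].astype(int),
        "label": t["label"].astype(str),
    })
    if (out["end"] < out["start"]).any():
        raise ValueError("degenerate (empty) interval in annotation")
    return out


# ---------------------------------------------------------------------------
# variant QC


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value on genotype counts.

    Conditional on the allele counts, heterozygote counts follow the exact
    distribution of Wigginton, Cutler & Abecasis (2005); the p-value sums the
    probabilities of all heterozygote counts no more probable than observed.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros(len(hets))
    # unnormalized log-probabilities via the exact conditional pmf:
    # P(het) ∝ 2^het * n! / (hom_r! het! hom_c!) with hom_r=(n_rare-het)/2
    for i, h in enumerate(hets):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logprob[i] = (h * math.log(2)
                      - math.lgamma(hom_r + 1) - math.lgamma(h + 1)
                      - math.lgamma(hom_c + 1))
    logprob -= logprob.max()
    prob = np.exp(logprob)
    prob /= prob.sum()
    obs = n_ab
    p_obs = prob[hets == obs][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def filter_variants(g: GenotypeMatrix, maf_min: float = 0.05,
                    hwe_alpha: float = 1e-4) -> GenotypeMatrix:
    """Drop SNPs failing MAF or exact-test HWE thresholds.

    Dosages are rounded to {0,1,2} to form genotype counts for the exact
    test; missing entries are excluded from both statistics.
    """
    keep = []
    n_maf = n_hwe = 0
    for snp_id in g.snp_ids:
        d = g.dosage[snp_id].dropna()
        if len(d) == 0:
            n_maf += 1
            continue
        af = d.mean() / 2.0
        maf = min(af, 1 - af)
        if maf < maf_min:
            n_maf += 1
            continue
        gt = d.round().astype(int).clip(0, 2)
        counts = gt.value_counts()
        p_hwe = hwe_exact_test(int(counts.get(0, 0)), int(counts.get(1, 0)),
                               int(counts.get(2, 0)))
        if p_hwe < hwe_alpha:
            n_hwe += 1
            continue
        keep.append(snp_id)
    log.info("filter_variants: removed %d SNPs by MAF < %g, %d by HWE p < %g; kept %d",
             n_maf, maf_min, n_hwe, hwe_alpha, len(keep))
    return g.subset_snps(keep)
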