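"""Functional-class enrichment of mQTL SNPs.

Two complementary tests: a permutation test comparing the functional-class
composition of the mQTL SNP set against same-sized draws from the pool of
non-associated SNPs, and a Fisher exact test of the overlap between mQTLs
and a trait's GWAS-catalog SNPs using the height catalog (the most
polygenic, best-powered anthropometric catalog) as the reference profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("metaboqtl")

__all__ = [
    "annotate_snps",
    "permutation_enrichment",
    "catalog_overlap_fisher",
    "EnrichmentResult",
    "CLASS_PRIORITY",
]

#: priority when a SNP overlaps intervals of several classes
CLASS_PRIORITY = ["exonic", "3'UTR", "5'UTR", "intronic", "intergenic"]


def annotate_snps(snps: pd.DataFrame, annotation: pd.DataFrame,
                  gene_window_bp: int = 10_000) -> pd.DataFrame:
    """Assign a functional class and (optionally) a gene to each SNP.

    ``snps`` needs columns chrom/pos (1-based) indexed by SNP id;
    ``annotation`` is a 1-based inclusive interval table (chrom, start, end,
    label) where labels are either functional classes or ``gene:<name>``
    intervals. A SNP inside overlapping class intervals takes the
    highest-priority class; a SNP within a gene body +/- ``gene_window_bp``
    is assigned that gene; SNPs matching nothing are ``intergenic``, and
    SNPs on chromosomes absent from the annotation are ``unannotated``.
    """
    is_gene = annotation["label"].str.startswith("gene:")
    classes = annotation[~is_gene]
    genes = annotation[is_gene]
    known_chroms = set(annotation["chrom"].astype(str))
    prio = {c: i for i, c in enumerate(CLASS_PRIORITY)}
    rows = []
    for snp_id, row in snps.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        if chrom not in known_chroms:
            rows.append((snp_id, "unannotated", None))
            continue
        hits = classes[(classes["chrom"] == chrom)
                       & (classes["start"] <= pos) & (pos <= classes["end"])]
        if len(hits):
            label = min(hits["label"], key=lambda c: prio.get(c, len(prio)))
        else:
            label = "intergenic"
        ghits = genes[(genes["chrom"] == chrom)
                      & (genes["start"] - gene_window_bp <= pos)
                      & (pos <= genes["end"] + gene_window_bp)]
        gene = ghits["label"].iloc[0].removeprefix("gene:") if len(ghits) else None
        rows.append((snp_id, label, gene))
    return pd.DataFrame(rows, columns=["snp", "class", "gene"]).set_index("snp")


@dataclass
class EnrichmentResult:
    """Observed vs permutation-null class counts with empirical p-values."""

    table: pd.DataFrame      # per class: observed, null_mean, null_sd, p
    n_perm: int

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_perm + 1)
        if ((self.table["p"] < floor - 1e-12) | (self.table["p"] > 1.0)).any():
            raise ValueError("empirical p outside [1/(n_perm+1), 1]")


def permutation_enrichment(target: pd.Series, background: pd.Series,
                           n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Permutation enrichment of class labels in a target SNP set.

    ``target`` and ``background`` map SNP id -> class label; the background
    pool holds SNPs with no significant association and must be disjoint
    from (and larger than) the target. Each permutation draws ``|target|``
    SNPs from the background without replacement; the per-class empirical
    p-value is (1 + #{null >= observed}) / (n_perm + 1), so it is floored at
    1/(n_perm+1) and never zero.
    """
    if len(background) < len(target):
        raise ValueError("background pool smaller than target set")
    overlap = target.index.intersection(background.index)
    if len(overlap):
        raise ValueError(f"target and background overlap: {list(overlap[:5])}")
    rng = np.random.default_rng(seed)
    classes = sorted(set(target) | set(background))
    obs = target.value_counts().reindex(classes, fill_value=0).to_numpy()
    bg = background.to_numpy()
    k = len(target)
    null = np.zeros((n_perm, len(classes)), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    bg_codes = np.fromiter((class_index[c] for c in bg), dtype=int, count=len(bg))
    for b in range(n_perm):
        draw = rng.choice(bg_codes, size=k, replace=False)
        null[b] = np.bincount(draw, minlength=len(classes))
    ge = (null >= obs[None, :]).sum(axis=0)
    p = (1.0 + ge) / (n_perm + 1.0)
    table = pd.DataFrame({
        "observed": obs,
        "null_mean": null.mean(axis=0),
        "null_sd": null.std(axis=0, ddof=1),
        "p": p,
    }, index=pd.Index(classes, name="class"))
    return EnrichmentResult(table, n_perm)


def catalog_overlap_fisher(mqtl_snps: set, trait_catalog: set,
                           height_catalog: set) -> tuple[float, float]:
    """One-sided Fisher exact test of mQTL overlap with a trait catalog,
    referenced against the height catalog.

    The 2x2 table is [[|mQTL∩trait|, |trait∖mQTL|],
    [|mQTL∩height|, |height∖mQTL|]]; the alternative is that the trait
    catalog overlaps mQTLs more than height does. Returns (odds ratio, p);
    the odds ratio is NaN when undefined (zero overlap row), with p = 1.
    """
    if not trait_catalog or not height_catalog:
        raise ValueError("trait and height catalogs must be non-empty")
    a = len(mqtl_snps & trait_catalog)
    b = len(trait_catalog - mqtl_snps)
    c = len(mqtl_snps & height_catalog)
    d = len(height_catalog - mqtl_snps)
    if a == 0 and c == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
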