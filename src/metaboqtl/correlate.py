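"""Covariate-adjusted Spearman association scans with BH-FDR, host-factor
summaries, and deterministic correlation-matrix clustering.

"Adjusting" for covariates is implemented as residualize-then-Spearman: each
feature is regressed on the covariates (OLS with intercept) and the rank
correlation is computed between residuals. The FDR family is the full a x b
grid of one scan call, mirroring per-category association tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix
from .preprocess import residualize

log = logging.getLogger("metaboqtl")

__all__ = [
    "adjusted_spearman_scan",
    "host_factor_scan",
    "cluster_correlation_matrix",
    "bh_adjust",
    "spearman_grid",
]

MIN_PAIRS = 10


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _rank_z(x: np.ndarray) -> np.ndarray:
    """Average ranks, centered and scaled to unit norm (constant -> zeros)."""
    r = stats.rankdata(x, axis=0)
    r = r - r.mean(axis=0)
    norm = np.sqrt((r ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, r / norm, 0.0)
    return out


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p by the t approximation (used for n > 10)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def spearman_grid(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman rho, p and pair counts between columns of a and b.

    Complete rows are used when the matrices have no missing values (fast
    matrix path); otherwise each pair falls back to its pairwise-complete
    observations.
    """
    A, B = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    n, ka = A.shape
    kb = B.shape[1]
    if not (np.isnan(A).any() or np.isnan(B).any()):
        za, zb = _rank_z(A), _rank_z(B)
        rho = za.T @ zb
        const = np.outer((za == 0).all(axis=0), np.ones(kb, bool)) | \
            np.outer(np.ones(ka, bool), (zb == 0).all(axis=0))
        rho[const] = np.nan
        p = np.where(np.isnan(rho) | (n <= MIN_PAIRS), np.nan, _spearman_p(rho, n))
        return rho, p, np.full((ka, kb), n)
    rho = np.full((ka, kb), np.nan)
    p = np.full((ka, kb), np.nan)
    npairs = np.zeros((ka, kb), dtype=int)
    for i in range(ka):
        for j in range(kb):
            ok = ~(np.isnan(A[:, i]) | np.isnan(B[:, j]))
            m = int(ok.sum())
            npairs[i, j] = m
            if m <= MIN_PAIRS:
                continue
            x, y = A[ok, i], B[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = stats.spearmanr(x, y).statistic
            rho[i, j] = r
            p[i, j] = _spearman_p(np.array(r), m)
    return rho, p, npairs


def adjusted_spearman_scan(a: FeatureMatrix, b: FeatureMatrix,
                           covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Covariate-adjusted Spearman scan over the full a x b feature grid.

    Returns an association table with one row per (feature_a, feature_b)
    pair: ``n_pairs``, ``rho``, ``p`` and BH-adjusted ``q`` (one adjustment
    family per call). Pairs with fewer than 10 complete observations or a
    zero-variance residual get undefined rho/p/q.
    """
    common = a.samples.intersection(b.samples)
    av = a.values.loc[common]
    bv = b.values.loc[common]
    if covariates is not None:
        cov = covariates.loc[common]
        av = residualize(FeatureMatrix(av, "other"), cov).values
        bv = residualize(FeatureMatrix(bv, "other"), cov).values
    rho, p, npairs = spearman_grid(av, bv)
    ia, ib = np.meshgrid(np.arange(av.shape[1]), np.arange(bv.shape[1]), indexing="ij")
    out = pd.DataFrame({
        "feature_a": av.columns.to_numpy()[ia.ravel()],
        "feature_b": bv.columns.to_numpy()[ib.ravel()],
        "n_pairs": npairs.ravel(),
        "rho": rho.ravel(),
        "p": p.ravel(),
    })
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def host_factor_scan(features: FeatureMatrix, factors: pd.DataFrame,
                     pre_adjust: pd.DataFrame | None = None,
                     alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-host-factor association scan with within-factor BH families.

    Each factor column (age, sex coded 0/1, BMI, contraceptive use 0/1...)
    is tested against every feature by the same rank procedure, optionally
    after residualizing the features on ``pre_adjust`` covariates. Returns
    the association table and a per-factor summary: fraction of features
    with q < alpha and, among those, the fraction with rho > 0.
    """
    assoc_parts = []
    summary_rows = []
    for factor in factors.columns:
        fac = FeatureMatrix(factors[[factor]].astype(float), "other")
        part = adjusted_spearman_scan(features, fac, pre_adjust)
        part = part.rename(columns={"feature_a": "feature", "feature_b": "factor"})
        part["factor"] = factor
        part["q"] = bh_adjust(part["p"].to_numpy())   # family = one factor
        assoc_parts.append(part)
        sig = part[part["q"] < alpha]
        denom = part["p"].notna().sum()
        summary_rows.append({
            "factor": factor,
            "n_features": int(denom),
            "n_significant": len(sig),
            "fraction_significant": len(sig) / denom if denom else np.nan,
            "fraction_positive": (sig["rho"] > 0).mean() if len(sig) else np.nan,
        })
    return pd.concat(assoc_parts, ignore_index=True), pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# hierarchical clustering of the correlation matrix


def _complete_linkage_order(X: np.ndarray) -> list[int]:
    """Leaf order from complete-linkage clustering on Euclidean distances.

    Deterministic tie-breaks: among equally distant cluster pairs the pair
    with the smallest (then second-smallest) minimum original member index
    merges first; when flattening, the smaller subtree comes first (ties by
    smallest member index). Undefined entries must be imputed by the caller.
    """
    k = X.shape[0]
    if k == 1:
        return [0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters: dict[int, list[int]] = {i: [i] for i in range(k)}
    dist = {(i, j): D[i, j] for i in range(k) for j in range(i + 1, k)}
    trees: dict[int, object] = {i: i for i in range(k)}
    while len(clusters) > 1:
        # pick min distance; ties by (min member of first, min member of second)
        best = min(dist.items(),
                   key=lambda kv: (kv[1], min(clusters[kv[0][0]]), min(clusters[kv[0][1]])))
        (i, j), _ = best
        a, b = sorted((i, j))
        members = clusters[a] + clusters[b]
        clusters[a] = members
        trees[a] = (trees[a], trees[b])
        del clusters[b], trees[b]
        dist = {key: v for key, v in dist.items() if b not in key}
        for other in clusters:
            if other == a:
                continue
            key = (min(a, other), max(a, other))
            dist[key] = max(D[np.ix_(members, clusters[other])].max(),
                           0.0)
    [tree] = trees.values()

    def flatten(node) -> list[int]:
        if isinstance(node, int):
            return [node]
        left, right = (flatten(node[0]), flatten(node[1]))
        if (len(left), min(left)) > (len(right), min(right)):
            left, right = right, left
        return left + right

    return flatten(tree)


def cluster_correlation_matrix(assoc: pd.DataFrame) -> tuple[list, list]:
    """Complete-linkage leaf orderings for the rows and columns of an
    association table's rho grid (undefined rho imputed as 0, logged)."""
    grid = assoc.pivot(index="feature_a", columns="feature_b", values="rho")
    n_undef = int(grid.isna().sum().sum())
    if n_undef:
        log.info("cluster_correlation_matrix: imputing %d undefined rho as 0", n_undef)
        grid = grid.fillna(0.0)
    row_order = [grid.index[i] for i in _complete_linkage_order(grid.to_numpy())]
    col_order = [grid.columns[i] for i in _complete_linkage_order(grid.to_numpy().T)]
    return row_order, col_order
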