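"""Metabolite QC: log10 transform, PCA-based sample outlier exclusion,
normality reporting and covariate residualization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import FeatureMatrix

log = logging.getLogger("metaboqtl")

__all__ = [
    "log_transform",
    "pca_outliers",
    "normality_report",
    "residualize",
    "ResidualizedMatrix",
]


def log_transform(m: FeatureMatrix, base: float = 10,
                  zero_policy: str = "half_min") -> FeatureMatrix:
    """Element-wise log of a non-negative feature matrix.

    Zeros are replaced by half the smallest positive value of the same
    feature under the ``half_min`` policy, or rejected under ``error``.
    Negative values are always rejected.
    """
    if zero_policy not in ("half_min", "error"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    vals = m.values.copy().astype(float)
    neg = (vals < 0).any(axis=0)
    if neg.any():
        raise ValueError(f"negative values in feature(s): {list(vals.columns[neg])}")
    for col in vals.columns:
        x = vals[col]
        zero = x == 0
        if zero.any():
            if zero_policy == "error":
                raise ValueError(f"zero values in feature {col!r} under zero_policy='error'")
            pos = x[x > 0]
            if pos.empty:
                raise ValueError(f"feature {col!r} is all zero; cannot apply half_min")
            vals.loc[zero, col] = pos.min() / 2.0
    out = np.log(vals) / np.log(base)
    return FeatureMatrix(out, m.platform, m.annotation)


def pca_outliers(m: FeatureMatrix, sd_threshold: float = 4.0
                 ) -> tuple[list, list, pd.DataFrame]:
    """Flag samples beyond ``sd_threshold`` SDs from the mean of PC1 or PC2.

    Features are z-scored before PCA (missing entries mean-imputed per
    feature, which lands them at the feature mean and is neutral for the
    component fit). Returns (kept ids, flagged ids, PC-score table).
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA outlier detection")
    vals = m.values.astype(float)
    n_missing = int(vals.isna().sum().sum())
    if n_missing:
        log.info("pca_outliers: mean-imputing %d missing entries", n_missing)
        vals = vals.fillna(vals.mean(axis=0))
    sd = vals.std(axis=0, ddof=1)
    keep_cols = sd[sd > 0].index
    if len(keep_cols) == 0:
        scores = pd.DataFrame(0.0, index=m.samples, columns=["PC1", "PC2"])
        return list(m.samples), [], scores
    z = (vals[keep_cols] - vals[keep_cols].mean(axis=0)) / sd[keep_cols]
    k = min(2, z.shape[0] - 1, z.shape[1])
    pcs = PCA(n_components=k, svd_solver="full").fit_transform(z.to_numpy())
    if pcs.shape[1] < 2:
        pcs = np.column_stack([pcs, np.zeros(len(z))])
    scores = pd.DataFrame(pcs[:, :2], index=m.samples, columns=["PC1", "PC2"])
    flagged_mask = np.zeros(len(scores), dtype=bool)
    for pc in ("PC1", "PC2"):
        mu, s = scores[pc].mean(), scores[pc].std(ddof=1)
        if s > 0:
            flagged_mask |= (np.abs(scores[pc] - mu) > sd_threshold * s).to_numpy()
    flagged = list(scores.index[flagged_mask])
    kept = list(scores.index[~flagged_mask])
    if flagged:
        log.info("pca_outliers: flagged %d sample(s): %s", len(flagged), flagged)
    return kept, flagged, scores


def normality_report(m: FeatureMatrix) -> pd.DataFrame:
    """Shapiro-Wilk W and p per feature (report only; no filtering).

    Constant features and features with fewer than 3 non-missing values get
    NaN statistics and are marked undefined.
    """
    rows = []
    for col in m.features:
        x = m.values[col].dropna().to_numpy()
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append((col, np.nan, np.nan, False))
            continue
        w, p = stats.shapiro(x)
        rows.append((col, float(w), float(p), True))
    return pd.DataFrame(rows, columns=["feature", "W", "p", "defined"]).set_index("feature")


@dataclass
class ResidualizedMatrix:
    """Per-feature OLS residuals on a shared covariate design."""

    values: pd.DataFrame
    covariates_used: list
    models: pd.DataFrame       # per-feature intercept + coefficients


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns via the QR diagonal
        _, rr = np.linalg.qr(design)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] <= tol]
        raise ValueError(f"rank-deficient covariates; collinear column(s): {bad or names}")


def residualize(m: FeatureMatrix, covariates: pd.DataFrame) -> ResidualizedMatrix:
    """Regress each feature on the covariates (plus intercept) and return
    residuals. Complete-case per feature; residuals are NaN where the feature
    or any covariate is missing."""
    cov = covariates.loc[m.samples]
    names = ["intercept"] + list(cov.columns)
    base_ok = ~cov.isna().any(axis=1)
    design_full = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    _check_full_rank(design_full[base_ok.to_numpy()], names)
    resid = pd.DataFrame(np.nan, index=m.samples, columns=m.features)
    coefs = pd.DataFrame(np.nan, index=m.features, columns=names)
    for col in m.features:
        y = m.values[col]
        ok = (base_ok & ~y.isna()).to_numpy()
        if ok.sum() <= len(names):
            continue
        X = design_full[ok]
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float)[ok], rcond=None)
        resid.loc[ok, col] = y.to_numpy(dtype=float)[ok] - X @ beta
        coefs.loc[col] = beta
    return ResidualizedMatrix(resid, list(cov.columns), coefs)
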