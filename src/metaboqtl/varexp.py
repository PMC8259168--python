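"""Explained-variance estimation: association pre-filtering, confounder
regression, collinearity removal, multivariate OLS and adjusted R^2.

The procedure estimates how much inter-individual variation in a response
(e.g. a stimulated cytokine level) is jointly explained by a family of
candidate features (e.g. metabolites): candidates are first screened by
covariate-adjusted Spearman p-value (0.001 for metabolite candidates, 0.05
for other feature classes), confounders are regressed out of response and
survivors, near-duplicate candidates (pairwise |Pearson r| above a
threshold) are greedily dropped, and the rest enter one multivariate linear
model whose adjusted R^2 is reported. Selection and fitting use the same
data, so the estimate carries selection optimism; the null-calibration test
suite bounds it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix
from .correlate import spearman_grid
from .preprocess import residualize

log = logging.getLogger("metaboqtl")

__all__ = ["adjusted_r2", "explain_variance", "VarExpResult", "CLASS_P_THRESHOLDS"]

#: screening p thresholds per candidate feature class
CLASS_P_THRESHOLDS = {"metabolite": 0.001, "other": 0.05}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    if n <= p + 1:
        raise ValueError(f"saturated model: n={n} <= p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VarExpResult:
    response: str
    kept_features: list
    dropped_collinear: list
    r2: float
    adj_r2: float
    n: int
    p_features: int

    @property
    def clamped_adj_r2(self) -> float:
        """Adjusted R^2 floored at 0 (explained variance is non-negative)."""
        return max(self.adj_r2, 0.0)


def explain_variance(response: pd.Series, candidates: FeatureMatrix,
                     covariates: pd.DataFrame | None = None,
                     p_threshold: float = 0.05,
                     collinearity_r: float = 0.9,
                     response_id: str = "response") -> VarExpResult:
    """Adjusted R^2 of a response on screened, decollinearized candidates.

    Steps: (1) covariate-adjusted Spearman screen at ``p_threshold``;
    (2) residualize response and selected candidates on the covariates;
    (3) greedily drop one of each candidate pair with |Pearson r| >
    ``collinearity_r`` (the one with the larger marginal screening p);
    (4) OLS of the residual response on the survivors, adjusted R^2.
    """
    common = candidates.samples.intersection(response.index)
    y = response.loc[common].astype(float)
    ok = y.notna()
    if covariates is not None:
        cov = covariates.loc[common]
        ok &= cov.notna().all(axis=1)
    y = y[ok]
    common = y.index
    n = len(common)
    if n < 30:
        raise ValueError(f"need n >= 30 complete observations, got {n}")
    cand_vals = candidates.values.loc[common]
    cov = covariates.loc[common] if covariates is not None else None

    # (1) screening on adjusted Spearman p
    yv = pd.DataFrame({response_id: y})
    if cov is not None:
        yr = residualize(FeatureMatrix(yv, "other"), cov).values
        cr = residualize(FeatureMatrix(cand_vals, "other"), cov).values
    else:
        yr, cr = yv, cand_vals
    _, pvals, _ = spearman_grid(cr, yr)
    pvals = pd.Series(pvals[:, 0], index=cand_vals.columns)
    selected = list(pvals.index[(pvals < p_threshold).fillna(False)])
    if not selected:
        return VarExpResult(response_id, [], [], 0.0, 0.0, n, 0)

    # (2) residual response and residual selected candidates
    y_res = yr[response_id].to_numpy(dtype=float)
    X = cr[selected].to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)

    # (3) greedy collinearity pruning, keeping the smaller marginal p
    order = sorted(range(len(selected)), key=lambda i: (pvals[selected[i]], selected[i]))
    corr = np.corrcoef(X, rowvar=False) if len(selected) > 1 else np.ones((1, 1))
    kept_idx: list[int] = []
    dropped: list[str] = []
    for i in order:
        if any(abs(corr[i, j]) > collinearity_r for j in kept_idx):
            dropped.append(selected[i])
        else:
            kept_idx.append(i)
    kept = [selected[i] for i in sorted(kept_idx)]
    if len(kept) >= n - 2:
        raise ValueError(f"over-parameterized: {len(kept)} features for n={n}")

    # (4) multivariate OLS and adjusted R^2
    Xk = X[:, sorted(kept_idx)]
    design = np.column_stack([np.ones(n), Xk])
    beta, *_ = np.linalg.lstsq(design, y_res, rcond=None)
    fitted = design @ beta
    ss_tot = ((y_res - y_res.mean()) ** 2).sum()
    ss_res = ((y_res - fitted) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    adj = adjusted_r2(r2, n, len(kept))
    log.info("explain_variance(%s): %d screened, %d kept, %d collinear dropped, "
             "adj R2=%.4f", response_id, len(selected), len(kept), len(dropped), adj)
    return VarExpResult(response_id, kept, dropped, r2, adj, n, len(kept))
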