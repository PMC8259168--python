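"""Two-sample Mendelian randomization.

Instruments are genome-wide significant, LD-independent exposure SNPs with
alleles harmonized between the exposure and outcome summary statistics.
Each instrument contributes a Wald ratio theta_j = betaY/betaX with
first-order standard error sigmaY/|betaX|; estimators combine the ratios:

* inverse-variance weighted (IVW): precision-weighted mean, the efficient
  estimator when every instrument is valid;
* weighted median: consistent when at least half the weight comes from
  valid instruments;
* simple / weighted mode: consistent when the largest homogeneous cluster
  of ratios is valid (ZEro Modal Pleiotropy Assumption), located as the
  argmax of a Gaussian kernel density over the ratios with a MAD-derived
  bandwidth.

Cochran's Q quantifies heterogeneity between the per-instrument ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, SummaryStats

log = logging.getLogger("metaboqtl")

__all__ = ["harmonize_and_select", "mr_estimate", "mr_all_methods", "cochran_q", "MRResult"]

METHODS = ("ivw", "weighted_median", "simple_mode", "weighted_mode")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def harmonize_and_select(exposure: SummaryStats, outcome: SummaryStats,
                         p_threshold: float = 5e-8, r2_threshold: float = 0.01,
                         ld_ref: GenotypeMatrix | None = None,
                         ratio_se: str = "first_order") -> pd.DataFrame:
    """Build the harmonized instrument table.

    Steps: (1) keep exposure SNPs with p < ``p_threshold``; (2) greedy LD
    pruning by exposure p at dosage r^2 < ``r2_threshold`` in ``ld_ref``
    (skipped when no reference is given, e.g. for analytically independent
    SNPs); (3) align the outcome's effect allele to the exposure's, flipping
    betaY and eaf when the alleles are swapped and dropping mismatches;
    (4) drop palindromic (A/T, C/G) SNPs with eaf in [0.42, 0.58], whose
    strand cannot be resolved from frequency.

    Returns per instrument: beta_x, se_x, beta_y, se_y, the Wald ratio
    ``wald``, its first-order se and the inverse-variance weight.
    """
    exp = exposure.table.set_index("snp")
    out = outcome.table.set_index("snp")
    attrition = {"candidates": len(exp)}
    sig = exp[exp["p"] < p_threshold].sort_values("p")
    attrition["p_threshold"] = len(sig)
    if ld_ref is not None:
        dosage = ld_ref.imputed_dosage()
        kept: list[str] = []
        for snp in sig.index:        # ascending exposure p
            if snp not in dosage.columns:
                continue
            x = dosage[snp].to_numpy()
            if x.std() == 0:
                continue
            independent = True
            for prev in kept:
                r = np.corrcoef(x, dosage[prev].to_numpy())[0, 1]
                if r ** 2 >= r2_threshold:
                    independent = False
                    break
            if independent:
                kept.append(snp)
        sig = sig.loc[kept]
    attrition["ld_prune"] = len(sig)

    rows = []
    for snp in sig.index:
        if snp not in out.index:
            continue
        e, o = sig.loc[snp], out.loc[snp]
        ea, oa = str(e["ea"]).upper(), str(e["oa"]).upper()
        oea, ooa = str(o["ea"]).upper(), str(o["oa"]).upper()
        if (oea, ooa) == (ea, oa):
            beta_y, eaf_y = o["beta"], o["eaf"]
        elif (oea, ooa) == (oa, ea):
            beta_y, eaf_y = -o["beta"], 1.0 - o["eaf"]
        else:
            log.info("harmonize: allele mismatch at %s (%s/%s vs %s/%s), dropped",
                     snp, ea, oa, oea, ooa)
            continue
        if _is_palindromic(ea, oa):
            lo, hi = PALINDROMIC_EAF_WINDOW
            if lo <= e["eaf"] <= hi or lo <= eaf_y <= hi:
                log.info("harmonize: palindromic %s with ambiguous eaf, dropped", snp)
                continue
        rows.append((snp, e["beta"], e["se"], beta_y, o["se"], e["eaf"]))
    attrition["harmonized"] = len(rows)
    if not rows:
        raise ValueError(f"no instruments survive selection; attrition: {attrition}")
    tab = pd.DataFrame(rows, columns=["snp", "beta_x", "se_x", "beta_y", "se_y", "eaf"])
    if (tab["beta_x"] == 0).any():
        raise ValueError("instrument with beta_x == 0 cannot form a Wald ratio")
    tab["wald"] = tab["beta_y"] / tab["beta_x"]
    if ratio_se == "first_order":
        tab["wald_se"] = tab["se_y"] / tab["beta_x"].abs()
    elif ratio_se == "second_order":
        # delta method including exposure uncertainty
        tab["wald_se"] = np.sqrt(tab["se_y"] ** 2 / tab["beta_x"] ** 2
                                 + tab["beta_y"] ** 2 * tab["se_x"] ** 2
                                 / tab["beta_x"] ** 4)
    else:
        raise ValueError(f"unknown ratio_se {ratio_se!r}")
    tab["weight"] = 1.0 / tab["wald_se"] ** 2
    log.info("harmonize_and_select: attrition %s", attrition)
    return tab.set_index("snp")


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    het_q: float | None = None
    het_df: int | None = None
    het_p: float | None = None


def _ivw(wald: np.ndarray, weight: np.ndarray) -> tuple[float, float]:
    est = float((weight * wald).sum() / weight.sum())
    se = float(np.sqrt(1.0 / weight.sum()))
    return est, se


def _weighted_median(wald: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(wald)
    b, w = wald[order], weight[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, cum, b))


def _mode(wald: np.ndarray, weight: np.ndarray | None, phi: float = 1.0) -> float:
    """Mode of a Gaussian kernel density over the ratios.

    Bandwidth h = phi * 0.9 * s * n^(-1/5) with s derived from the median
    absolute deviation (MAD / 0.6745); degenerate spreads collapse to the
    median.
    """
    n = len(wald)
    s = stats.median_abs_deviation(wald) / 0.6745
    if s == 0:
        return float(np.median(wald))
    h = phi * 0.9 * s * n ** (-1 / 5)
    w = np.ones(n) if weight is None else weight
    grid = np.linspace(wald.min() - 3 * h, wald.max() + 3 * h, 2048)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - wald[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


_MIN_INSTRUMENTS = {"ivw": 1, "weighted_median": 3, "simple_mode": 3, "weighted_mode": 3}


def mr_estimate(instruments: pd.DataFrame, method: str = "ivw",
                n_boot: int = 1000, seed: int = 0, phi: float = 1.0,
                random_effects: bool = False) -> MRResult:
    """Causal estimate from a harmonized instrument table by one method.

    IVW standard errors are fixed-effect by default; ``random_effects=True``
    inflates them by sqrt(Q/df) when Q/df > 1. Weighted-median and mode
    standard errors come from a seeded parametric bootstrap that redraws
    betaX and betaY from their sampling distributions.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    n = len(instruments)
    if n < _MIN_INSTRUMENTS[method]:
        raise ValueError(f"{method} needs >= {_MIN_INSTRUMENTS[method]} instruments, got {n}")
    wald = instruments["wald"].to_numpy()
    weight = instruments["weight"].to_numpy()

    if method == "ivw":
        est, se = _ivw(wald, weight)
        het_q = het_df = het_p = None
        if n >= 2:
            het_q, het_df, het_p = cochran_q(instruments)
            if random_effects and het_q / het_df > 1.0:
                se *= np.sqrt(het_q / het_df)
        p = 2.0 * stats.norm.sf(abs(est / se))
        return MRResult(method, est, se, float(p), n, het_q, het_df, het_p)

    def point(bx: np.ndarray, by: np.ndarray) -> float:
        ratios = by / bx
        w = (bx ** 2) / instruments["se_y"].to_numpy() ** 2
        if method == "weighted_median":
            return _weighted_median(ratios, w)
        if method == "simple_mode":
            return _mode(ratios, None, phi)
        return _mode(ratios, w, phi)

    bx0 = instruments["beta_x"].to_numpy()
    by0 = instruments["beta_y"].to_numpy()
    est = point(bx0, by0)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = bx0 + rng.standard_normal(n) * instruments["se_x"].to_numpy()
        by = by0 + rng.standard_normal(n) * instruments["se_y"].to_numpy()
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        boots[b] = point(bx, by)
    se = float(boots.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else (0.0 if est else 1.0)
    return MRResult(method, float(est), se, float(p), n)


def mr_all_methods(instruments: pd.DataFrame, n_boot: int = 1000,
                   seed: int = 0) -> dict[str, MRResult]:
    """All four estimators on one instrument table (shared bootstrap seed)."""
    return {m: mr_estimate(instruments, m, n_boot=n_boot, seed=seed) for m in METHODS}


def cochran_q(instruments: pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the Wald ratios around the IVW estimate.

    Q = sum w_j (theta_j - theta_IVW)^2 ~ chi-square with n-1 df under
    homogeneity.
    """
    n = len(instruments)
    if n < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    wald = instruments["wald"].to_numpy()
    weight = instruments["weight"].to_numpy()
    est, _ = _ivw(wald, weight)
    q = float((weight * (wald - est) ** 2).sum())
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))
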