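"""Bayesian colocalization of two traits over one region.

Per-SNP evidence is summarized by Wakefield's approximate Bayes factor,
computed from the effect estimate and its standard error under a Gaussian
effect prior of standard deviation W. The posterior over the five standard
hypotheses —

* H0: no association with either trait,
* H1/H2: association with trait 1/2 only,
* H3: both traits associated, distinct causal variants,
* H4: both traits associated, one shared causal variant —

follows from summing per-configuration likelihood ratios with single-variant
prior probabilities p1, p2 (trait-specific) and p12 (shared). All sums are
done in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datatypes import SummaryStats

log = logging.getLogger("metaboqtl")

__all__ = ["wakefield_labf", "coloc_posteriors", "coloc_summary_stats",
           "se_from_p_eaf_n", "ColocResult"]

#: conventional effect-prior SDs: quantitative traits, case-control (log-odds)
PRIOR_SD = {"quantitative": 0.15, "case_control": 0.2}
HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


def wakefield_labf(beta, se, prior_sd_W: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    With V = se^2, z = beta/se and W = prior_sd_W^2:
    log ABF = 0.5 * [log(V/(V+W)) + z^2 * W/(V+W)].
    Vectorized over SNPs.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be strictly positive")
    V = se ** 2
    W = prior_sd_W ** 2
    z2 = (beta / se) ** 2
    r = W / (V + W)
    return 0.5 * (np.log(V / (V + W)) + z2 * r)


def se_from_p_eaf_n(p, eaf, n) -> np.ndarray:
    """Reconstruct an effect standard error from p, allele frequency and n.

    Uses the standard large-sample approximation for a unit-variance trait,
    se = 1/sqrt(2 f (1-f) (n + z^2)) with z the |quantile| of p — a
    lower-fidelity fallback for summary tables that omit beta/se.
    """
    p = np.asarray(p, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    z = np.abs(_norm_ppf_half(p))
    log.info("reconstructing se from p/eaf/n (lower fidelity than reported se)")
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z ** 2))


def _norm_ppf_half(p):
    from scipy.stats import norm
    return norm.ppf(np.asarray(p, dtype=float) / 2.0)


@dataclass
class ColocResult:
    pp: dict                  # hypothesis -> posterior probability
    labf1: np.ndarray
    labf2: np.ndarray
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior probabilities sum to {total}, not 1")
        if any(v < 0 for v in self.pp.values()):
            raise ValueError("negative posterior probability")

    @property
    def m(self) -> int:
        return len(self.labf1)

    def snp_h4_posterior(self) -> np.ndarray:
        """Per-SNP posterior of being the shared causal variant given H4."""
        joint = self.labf1 + self.labf2
        w = np.exp(joint - logsumexp(joint))
        return w


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(labf1, labf2, p1: float = 1e-4, p2: float = 1e-4,
                     p12: float = 1e-5) -> ColocResult:
    """Posterior probabilities of H0-H4 from per-SNP log-ABFs of two traits.

    Uses the standard configuration sums: with L1 = sum e^labf1,
    L2 = sum e^labf2 and L12 = sum e^(labf1+labf2), the unnormalized
    hypothesis weights are (1, p1 L1, p2 L2, p1 p2 (L1 L2 - L12), p12 L12);
    the H3 mass excludes same-SNP pairs. Everything is evaluated with
    log-sum-exp; a (tiny) negative H3 mass from float cancellation is
    clamped to zero and logged.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape:
        raise ValueError("labf1 and labf2 must have equal length")
    if labf1.ndim != 1 or len(labf1) < 1:
        raise ValueError("need a 1-d vector of at least one SNP")
    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    # H3: all ordered pairs with distinct SNPs = L1*L2 - L12
    lh3 = _log_diff_exp(l1 + l2, l12)
    if len(labf1) == 1:
        lh3 = -np.inf
    logw = np.array([
        0.0,
        np.log(p1) + l1,
        np.log(p2) + l2,
        np.log(p1) + np.log(p2) + lh3,
        np.log(p12) + l12,
    ])
    pp = np.exp(logw - logsumexp(logw))
    return ColocResult(dict(zip(HYPOTHESES, pp)), labf1, labf2, p1, p2, p12)


def coloc_summary_stats(stats1: SummaryStats, stats2: SummaryStats,
                        p1: float = 1e-4, p2: float = 1e-4,
                        p12: float = 1e-5) -> ColocResult:
    """Colocalize two traits' summary statistics over their shared SNPs.

    The effect-prior SD is chosen per trait type (0.15 quantitative, 0.2
    case-control). SNPs are matched by id; order follows trait 1.
    """
    t1 = stats1.table.set_index("snp")
    t2 = stats2.table.set_index("snp")
    shared = t1.index.intersection(t2.index)
    if len(shared) == 0:
        raise ValueError("no shared SNPs between the two traits")
    labf1 = wakefield_labf(t1.loc[shared, "beta"], t1.loc[shared, "se"],
                           PRIOR_SD[stats1.trait_type])
    labf2 = wakefield_labf(t2.loc[shared, "beta"], t2.loc[shared, "se"],
                           PRIOR_SD[stats2.trait_type])
    return coloc_posteriors(labf1, labf2, p1, p2, p12)
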