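"""Synthetic cohort generator.

Emulates the statistical structure of a population-cohort multi-omics study:
LD-blocked biallelic genotypes under Hardy-Weinberg equilibrium, log-normal
metabolite features with planted SNP and covariate effects, cytokine
responses driven by metabolites and SNPs, and paired exposure/outcome GWAS
summary statistics under null, shared-causal and distinct-causal scenarios.

Every generator takes an integer seed and is bit-reproducible. Planted
parameters are returned in a :class:`TruthLedger` so that downstream
estimators can be tested for recovery.

The LD model is deliberately simple: a latent standard-normal haplotype
process with first-order autoregressive correlation ``rho`` inside each
block, thresholded at the allele-frequency quantile. Two independent latent
haplotypes per individual are summed into a dosage, which makes the
genotypes Hardy-Weinberg by construction and gives adjacent-SNP r^2 that is
tunable through ``rho`` without coalescent machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, FeatureMatrix, SummaryStats

__all__ = [
    "TruthLedger",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_metabolome",
    "simulate_immune",
    "simulate_gwas_pair",
    "simulate_gwas_pair_cohort",
    "paper_like_fractions",
    "MR_LARGE_N_PRESET",
    "COLOC_REGION_PRESET",
]

LN10 = np.log(10.0)


@dataclass
class TruthLedger:
    """Record of every planted parameter of one simulated dataset."""

    snp_effects: list = field(default_factory=list)          # (snp, feature, beta in SD units)
    feature_covariate_effects: list = field(default_factory=list)  # (covariate, feature, beta)
    causal_effect_theta: float | None = None                 # outcome units per exposure SD
    scenario: str | None = None                              # null | shared_causal | distinct_causal
    target_genetic_variance: dict = field(default_factory=dict)    # feature -> fraction
    causal_snps_exposure: list = field(default_factory=list)
    causal_snps_outcome: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for feat, f in self.target_genetic_variance.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"target_genetic_variance[{feat}] outside [0,1]")
        if self.scenario is not None and self.scenario not in (
                "null", "shared_causal", "distinct_causal"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(n_samples: int, blocks: list[dict], seed: int) -> GenotypeMatrix:
    """LD-blocked biallelic genotypes.

    Each block spec is ``{"n_snps": int, "maf_range": (lo, hi),
    "rho": float}`` with ``maf_range`` inside [0.05, 0.5] and ``rho`` in
    [0, 1). Blocks are placed on separate chromosomes, so cross-block LD is
    exactly zero; within a block adjacent SNPs share latent AR(1) correlation
    ``rho`` on the haplotype scale.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    dos_cols: list[np.ndarray] = []
    meta: list[tuple] = []
    alleles = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    snp_counter = 0
    for bi, block in enumerate(blocks):
        m = int(block["n_snps"])
        lo, hi = block.get("maf_range", (0.05, 0.5))
        rho = float(block.get("rho", 0.0))
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range {(lo, hi)} outside [0.05, 0.5]")
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"rho {rho} outside [0, 1)")
        mafs = rng.uniform(lo, hi, size=m)
        thresholds = stats.norm.ppf(1.0 - mafs)     # latent > threshold ⇒ alt allele
        dosage = np.zeros((n_samples, m))
        for _hap in range(2):                       # two independent haplotypes ⇒ HWE
            z = rng.standard_normal((n_samples, m))
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho ** 2) * z[:, j]
            dosage += (z > thresholds[None, :]).astype(float)
        dos_cols.append(dosage)
        for j in range(m):
            ref, alt = alleles[snp_counter % len(alleles)]
            meta.append((f"rs{snp_counter:06d}", str(bi + 1), 1 + j * 1000, ref, alt))
            snp_counter += 1
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "ref", "alt"]).set_index("snp")
    samples = pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample")
    dosage = pd.DataFrame(np.hstack(dos_cols), index=samples, columns=snps.index)
    return GenotypeMatrix(dosage, snps)


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(n_samples: int, seed: int,
                        samples: pd.Index | None = None) -> pd.DataFrame:
    """Age / sex / contraceptive-use table for a young-adult cohort.

    Age is a mixture (80% 18-30, 20% 30-75, mirroring a student-heavy
    cohort); sex is 0 = male, 1 = female (55% female); contraceptive use is
    coded 0/1 and only nonzero among women.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample")
    young = rng.random(n_samples) < 0.8
    age = np.where(young, rng.uniform(18, 30, n_samples), rng.uniform(30, 75, n_samples))
    sex = (rng.random(n_samples) < 0.55).astype(float)
    contraceptive = sex * (rng.random(n_samples) < 0.45).astype(float)
    return pd.DataFrame(
        {"age": np.round(age).astype(float), "sex": sex, "contraceptive": contraceptive},
        index=samples,
    )


# ---------------------------------------------------------------------------
# metabolome


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_metabolome(
    genotypes: GenotypeMatrix,
    n_features: int,
    planted: list[dict],
    covariates: pd.DataFrame | None = None,
    covariate_effects: list[tuple] | None = None,
    seed: int = 0,
    platform: str = "GM",
) -> tuple[FeatureMatrix, pd.DataFrame, TruthLedger]:
    """Log-normal metabolite features with planted genetic variance fractions.

    Each planted entry ``{"snp": id, "feature": id, "variance_fraction": f}``
    contributes a standardized-dosage term whose expected share of the
    latent-scale variance is ``f``; covariate terms (standardized internally)
    and Gaussian noise fill the rest of a unit variance budget. The latent
    Gaussian is exponentiated, so emitted values are strictly positive and a
    base-10 log transform downstream restores linearity (an affine rescaling
    that leaves every variance fraction unchanged).

    When ``covariate_effects`` is None, effects emulating a real cohort are
    drawn: sex affects ~60% of features, contraceptive use ~30%, age ~25%,
    each with a modest standardized effect.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    if covariates is None:
        covariates = simulate_covariates(n, seed=rng.integers(2 ** 31),
                                         samples=genotypes.samples)
    feature_ids = [f"met_{j:04d}" for j in range(n_features)]
    by_feature: dict[str, list[tuple[str, float]]] = {f: [] for f in feature_ids}
    for ent in planted:
        snp, feat, f = ent["snp"], ent["feature"], float(ent["variance_fraction"])
        if snp not in genotypes.snp_ids:
            raise ValueError(f"planted snp {snp!r} not in genotype matrix")
        if feat not in by_feature:
            raise ValueError(f"planted feature {feat!r} not among the {n_features} features")
        if not 0.0 < f < 1.0:
            raise ValueError(f"variance_fraction {f} outside (0,1)")
        by_feature[feat].append((snp, f))

    cov_std = covariates.apply(_standardize, raw=True)
    if covariate_effects is None:
        covariate_effects = []
        probs = {"sex": 0.60, "contraceptive": 0.30, "age": 0.25}
        for feat in feature_ids:
            for cov, prob in probs.items():
                if cov in covariates.columns and rng.random() < prob:
                    beta = rng.choice([-1, 1]) * rng.uniform(0.1, 0.3)
                    covariate_effects.append((cov, feat, float(beta)))
    gamma: dict[str, list[tuple[str, float]]] = {f: [] for f in feature_ids}
    for cov, feat, beta in covariate_effects:
        gamma[feat].append((cov, float(beta)))

    ledger = TruthLedger()
    values = np.empty((n, n_features))
    for j, feat in enumerate(feature_ids):
        latent = np.zeros(n)
        gen_var = 0.0
        for snp, f in by_feature[feat]:
            z = _standardize(genotypes.imputed_dosage()[snp].to_numpy())
            beta = np.sqrt(f)
            latent += beta * z
            gen_var += f
            ledger.snp_effects.append((snp, feat, float(beta)))
            ledger.target_genetic_variance[feat] = (
                ledger.target_genetic_variance.get(feat, 0.0) + f)
        if gen_var >= 1.0:
            raise ValueError(f"variance fractions for {feat} sum to {gen_var} >= 1")
        cov_var = 0.0
        for cov, beta in gamma[feat]:
            latent += beta * cov_std[cov].to_numpy()
            cov_var += beta ** 2
            ledger.feature_covariate_effects.append((cov, feat, beta))
        noise_var = 1.0 - gen_var - cov_var
        if noise_var <= 0:
            raise ValueError(
                f"genetic + covariate variance for {feat} leaves no noise budget")
        latent += rng.standard_normal(n) * np.sqrt(noise_var)
        values[:, j] = np.exp(latent)
    fm = FeatureMatrix(pd.DataFrame(values, index=genotypes.samples, columns=feature_ids),
                       platform)
    return fm, covariates, ledger


# ---------------------------------------------------------------------------
# immune phenotypes


def simulate_immune(
    metabolome: FeatureMatrix,
    genotypes: GenotypeMatrix,
    mapping: list[dict],
    noise_sd: float = 1.0,
    seed: int = 0,
    cytokine_ids: list[str] | None = None,
) -> tuple[FeatureMatrix, TruthLedger]:
    """Cytokine responses as linear mixes of metabolite and SNP drivers.

    Mapping entries ``{"source": id, "cytokine": id, "beta": b}``; a source
    id may name a metabolite (used on the log scale, standardized) or a SNP
    (standardized dosage). Cytokines absent from the mapping are pure noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = metabolome.n_samples
    if cytokine_ids is None:
        cytokine_ids = sorted({ent["cytokine"] for ent in mapping}) or ["cyt_000"]
    sources: dict[str, np.ndarray] = {}

    def source_vector(sid: str) -> np.ndarray:
        if sid in sources:
            return sources[sid]
        if sid in metabolome.features:
            v = _standardize(np.log10(metabolome.values[sid].to_numpy()))
        elif sid in genotypes.snp_ids:
            v = _standardize(genotypes.imputed_dosage()[sid].to_numpy())
        else:
            raise ValueError(f"unknown source id {sid!r}")
        sources[sid] = v
        return v

    ledger = TruthLedger()
    cols = {}
    for cyt in cytokine_ids:
        y = rng.standard_normal(n) * noise_sd
        for ent in mapping:
            if ent["cytokine"] != cyt:
                continue
            beta = float(ent["beta"])
            y = y + beta * source_vector(ent["source"])
            ledger.snp_effects.append((ent["source"], cyt, beta))
        cols[cyt] = y
    fm = FeatureMatrix(pd.DataFrame(cols, index=metabolome.samples), "cytokine")
    return fm, ledger


# ---------------------------------------------------------------------------
# summary statistics


def _make_summary(table: dict, trait_type: str = "quantitative",
                  case_fraction: float | None = None) -> SummaryStats:
    return SummaryStats(pd.DataFrame(table), trait_type, case_fraction)


def simulate_gwas_pair(
    scenario: str,
    m_snps: int,
    n_exposure: int,
    n_outcome: int,
    theta: float,
    seed: int,
    n_causal: int = 1,
    exposure_fraction: float = 0.03,
) -> tuple[SummaryStats, SummaryStats, TruthLedger]:
    """Paired exposure/outcome GWAS summary statistics.

    Effects are generated analytically: the observed beta of each SNP is
    drawn from Normal(true beta, SE^2) with SE = 1/sqrt(2 p (1-p) n) for a
    unit-variance trait — the standard large-sample standard error of a
    per-allele effect. Under ``shared_causal`` the ``n_causal`` causal SNPs
    act on both traits with outcome beta = theta x exposure beta; under
    ``distinct_causal`` exposure and outcome causal SNPs are disjoint; under
    ``null`` no SNP is causal for either trait (theta must then be 0).

    ``exposure_fraction`` is the exposure variance explained per causal SNP
    (default 3%, the order of magnitude of a strong metabolite QTL such as
    the FADS locus on arachidonic acid).
    """
    if scenario not in ("null", "shared_causal", "distinct_causal"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "null" and theta != 0.0:
        raise ValueError("theta must be 0 in the null scenario")
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    if n_exposure < 100 or n_outcome < 100:
        raise ValueError("sample sizes must be >= 100")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, m_snps)
    var_g = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_g * n_exposure)
    se_y = 1.0 / np.sqrt(var_g * n_outcome)

    true_x = np.zeros(m_snps)
    true_y = np.zeros(m_snps)
    ledger = TruthLedger(scenario=scenario, causal_effect_theta=theta)
    if scenario != "null":
        need = n_causal if scenario == "shared_causal" else 2 * n_causal
        if need > m_snps:
            raise ValueError("not enough SNPs for the requested causal count")
        picks = rng.choice(m_snps, size=need, replace=False)
        exp_idx = picks[:n_causal]
        signs = rng.choice([-1.0, 1.0], size=n_causal)
        true_x[exp_idx] = signs * np.sqrt(exposure_fraction / var_g[exp_idx])
        if scenario == "shared_causal":
            true_y[exp_idx] = theta * true_x[exp_idx]
            out_idx = exp_idx
        else:
            out_idx = picks[n_causal:]
            osigns = rng.choice([-1.0, 1.0], size=n_causal)
            true_y[out_idx] = osigns * np.sqrt(exposure_fraction / var_g[out_idx])
        ledger.causal_snps_exposure = [f"snp_{i:04d}" for i in np.sort(exp_idx)]
        ledger.causal_snps_outcome = [f"snp_{i:04d}" for i in np.sort(out_idx)]

    beta_x = true_x + rng.standard_normal(m_snps) * se_x
    beta_y = true_y + rng.standard_normal(m_snps) * se_y
    ids = [f"snp_{i:04d}" for i in range(m_snps)]
    base = dict(snp=ids, chrom="11", pos=1_000_000 + 1000 * np.arange(m_snps),
                ea="A", oa="G", eaf=maf)
    exposure = _make_summary({**base, "beta": beta_x, "se": se_x,
                              "p": 2 * stats.norm.sf(np.abs(beta_x / se_x)),
                              "n": n_exposure})
    outcome = _make_summary({**base, "beta": beta_y, "se": se_y,
                             "p": 2 * stats.norm.sf(np.abs(beta_y / se_y)),
                             "n": n_outcome})
    return exposure, outcome, ledger


def simulate_gwas_pair_cohort(
    scenario: str,
    m_snps: int,
    n_exposure: int,
    n_outcome: int,
    theta: float,
    seed: int,
    n_causal: int = 1,
    exposure_fraction: float = 0.03,
) -> tuple[SummaryStats, SummaryStats, TruthLedger]:
    """Cohort-based cross-check path for :func:`simulate_gwas_pair`.

    Simulates two independent cohorts of individual-level genotypes, builds
    the exposure from its causal SNPs and the outcome from theta x exposure
    genetic value plus noise, and runs an actual per-SNP regression in each
    cohort. Slower but makes no analytic shortcut; used to validate the
    analytic generator.
    """
    if scenario != "shared_causal":
        raise ValueError("cohort-based path implemented for shared_causal only")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, m_snps)
    causal = rng.choice(m_snps, size=n_causal, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    var_g = 2.0 * maf * (1.0 - maf)
    b = np.zeros(m_snps)
    b[causal] = signs * np.sqrt(exposure_fraction / var_g[causal])
    ids = [f"snp_{i:04d}" for i in range(m_snps)]
    ledger = TruthLedger(scenario=scenario, causal_effect_theta=theta,
                         causal_snps_exposure=[ids[i] for i in np.sort(causal)],
                         causal_snps_outcome=[ids[i] for i in np.sort(causal)])

    def one_cohort(n: int, is_outcome: bool) -> dict:
        g = rng.binomial(2, maf, size=(n, m_snps)).astype(float)
        genetic = g @ b
        noise_sd = np.sqrt(max(1.0 - n_causal * exposure_fraction, 0.05))
        exposure_trait = genetic + rng.standard_normal(n) * noise_sd
        if is_outcome:
            # outcome depends on the exposure's genetic value only (no
            # horizontal pleiotropy), plus independent outcome noise
            y = theta * genetic + rng.standard_normal(n)
        else:
            y = exposure_trait
        betas = np.empty(m_snps)
        ses = np.empty(m_snps)
        for j in range(m_snps):
            x = g[:, j] - g[:, j].mean()
            sxx = (x ** 2).sum()
            beta = (x * (y - y.mean())).sum() / sxx
            resid = (y - y.mean()) - beta * x
            s2 = (resid ** 2).sum() / (n - 2)
            betas[j] = beta
            ses[j] = np.sqrt(s2 / sxx)
        return dict(snp=ids, chrom="11", pos=1_000_000 + 1000 * np.arange(m_snps),
                    ea="A", oa="G", eaf=maf, beta=betas, se=ses,
                    p=2 * stats.t.sf(np.abs(betas / ses), n - 2), n=n)

    exposure = _make_summary(one_cohort(n_exposure, is_outcome=False))
    outcome = _make_summary(one_cohort(n_outcome, is_outcome=True))
    return exposure, outcome, ledger


# ---------------------------------------------------------------------------
# presets

#: instrument-recovery preset: 8 independent shared-causal SNPs of ~3%
#: exposure variance each at n = 200k per cohort, sized (per-ratio SE ~0.013,
#: IVW SE ~0.005) so that even the mode estimators resolve theta to ~0.01
MR_LARGE_N_PRESET = dict(m_snps=200, n_exposure=200_000, n_outcome=200_000,
                         n_causal=8, exposure_fraction=0.03)

#: colocalization presets: one strong causal variant (or none) in a 100-SNP
#: region; the shared scenario uses a substantial outcome effect, as a locus
#: must be genome-wide significant in both traits to enter colocalization
COLOC_REGION_PRESET = dict(m_snps=100, n_exposure=50_000, n_outcome=50_000,
                           theta=0.5, n_causal=1)


def paper_like_fractions(n_features: int, rng: np.random.Generator,
                         median: float = 0.081,
                         low: float = 0.013, high: float = 0.676) -> np.ndarray:
    """Genetic-variance fractions spanning ~1-70% with a fixed median.

    Drawn log-normal around ``median`` and truncated to [low, high]; the
    returned vector is rescaled in log space so its sample median equals
    ``median`` exactly, emulating the reported distribution of per-metabolite
    genetic variance.
    """
    f = np.exp(np.log(median) + 0.9 * rng.standard_normal(n_features))
    f = np.clip(f, low, high)
    # pin the sample median without disturbing the spread
    f = np.exp(np.log(f) + (np.log(median) - np.log(np.median(f))))
    return np.clip(f, low, high)
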