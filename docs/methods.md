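# Methods

`metaboqtl` re-implements, as a tested library, the statistical chain used
to integrate circulating-metabolome measurements with genotypes and deeply
phenotyped immune function in a population cohort: covariate-adjusted
association screening, explained-variance decomposition, metabolite-QTL
(mQTL) mapping, functional enrichment, Bayesian colocalization, two-sample
Mendelian randomization (MR), and a cross-validated prediction comparison.
Because the underlying cohort data are access-controlled, every stage is
exercised against a synthetic-cohort generator whose statistical structure
matches what the analyses assume, with all planted parameters recorded in a
truth ledger for recovery testing.

## The synthetic cohort

**Genotypes.** Each LD block lives on its own chromosome. Two independent
latent standard-normal haplotype vectors per individual follow a
first-order autoregressive process with correlation `rho` across adjacent
SNPs; thresholding each at the Φ⁻¹(1−MAF) quantile and summing yields
dosages in {0,1,2} that satisfy Hardy–Weinberg equilibrium by construction
while giving tunable adjacent-SNP r². MAFs are drawn uniformly inside a
block's range, bounded below at 0.05 to mirror standard GWAS QC. This is
deliberately simpler than coalescent simulation: recombination maps,
population structure and imputation uncertainty are not modelled, so tests
passing here say nothing about robustness to stratification or imputation
error.

**Metabolites.** A feature is a latent Gaussian
`Σ_g β_g·z(dosage_g) + Σ_c γ_c·z(covariate_c) + ε`, exponentiated so emitted
values are positive and log-normal — making the pipeline's base-10 log
transform a real (variance-fraction-preserving) step rather than a no-op.
Genetic effects are parameterized by *variance fraction* rather than raw
slope: `β_g = √f_g` against a unit total-variance budget, so a planted
`f = 0.08` is directly comparable with per-metabolite genetic variance
percentages. Default covariate effects emulate a young-adult cohort: sex
affects ~60 % of features, contraceptive use ~30 %, age ~25 %, each with a
standardized effect of 0.1–0.3. The preset fraction distribution is
log-normal with sample median pinned at 8.1 % and support clipped to
[1.3 %, 67.6 %].

**Cytokine responses** are linear mixes of standardized metabolite
(log-scale) and SNP sources plus Gaussian noise — the assay noise model is
an assumption, as the measurement error structure of stimulation assays is
not specified anywhere we could anchor it.

**GWAS summary pairs** are generated analytically: observed β ~
Normal(true β, SE²) with SE = 1/√(2p(1−p)n) per SNP, which is orders of
magnitude faster than simulating two cohorts and sufficient for
colocalization/MR testing. A cohort-based generator
(`simulate_gwas_pair_cohort`) exists purely as a cross-check and is tested
for agreement. Scenarios: `shared_causal` (outcome β = θ × exposure β at
the same causal SNPs), `distinct_causal` (disjoint causal sets), `null`
(θ must be 0). Two presets matter:

* `COLOC_REGION_PRESET` — one causal SNP in a 100-SNP region, θ = 0.5,
  n = 50 000 per trait. A region only enters colocalization when both
  traits are strongly associated there, so the preset uses a substantial
  shared effect; with θ as small as −0.07 the outcome z-score at n = 50 000
  is ≈ 2.7 and the correct verdict is "exposure only" (H1), not H4.
* `MR_LARGE_N_PRESET` — 8 independent causal SNPs of ~3 % exposure variance
  each (the order of a strong lipid-pathway metabolite QTL), n = 200 000
  per cohort. Sized by a power calculation: the mode estimators' SE is
  roughly twice the IVW SE, so per-ratio SE ≈ 1/√(f·n) ≈ 0.013 keeps all
  four estimators within ±0.02 of θ at 2σ.

## Stage-by-stage notes

**QC.** Metabolite values are log10-transformed (zeros → half the smallest
positive value of that feature, or an error, by policy). PCA outliers:
features are z-scored (missing entries mean-imputed), and a sample is
flagged when its PC1 *or* PC2 score is > 4 SD from the mean — the OR
reading is the conservative QC interpretation. Shapiro–Wilk normality is
reported per feature, never used as a filter.

**Adjusted correlation.** "Correcting for" age, sex and contraceptive use
is implemented as residualize-then-Spearman: each feature is regressed on
the covariates (OLS with intercept, complete-case per feature) and the
rank correlation is computed between residuals. Ties get average ranks;
p-values use the t approximation, applied only when > 10 paired
observations exist. BH-FDR is applied across the full a×b grid of one scan
call (one family per feature-category pairing). Correlation heat-map
ordering comes from complete-linkage clustering on Euclidean distances
between rho-vectors, hand-implemented with deterministic tie-breaks
(lowest-original-index pair merges first; smaller subtree flattens first)
because library implementations leave tie order unspecified; it is
cross-checked against SciPy on tie-free inputs.

**Explained variance.** Candidates are screened by adjusted-Spearman p
(0.001 for metabolite candidates, 0.05 for other classes), response and
survivors are residualized on the covariates, near-duplicates (pairwise
|Pearson r| > 0.9, configurable) are greedily dropped keeping the smaller
marginal p, and one multivariate OLS yields adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1), clamped at 0 for reporting (the raw value is
retained). Selection and fitting use the same data, so the estimate is
optimistic by construction. This optimism is material: with 200 null
candidates at n = 500 a 0.05 screening threshold yields mean adjusted R²
≈ 0.08 from selection alone, while the strict 0.001 metabolite threshold
keeps it below 0.05 — one concrete reason the tight metabolite screening
cut-off matters. The null-calibration test pins this behaviour.

**mQTL scan.** Features (log scale, z-scored so slopes are in feature-SD
per allele) and mean-imputed dosages are residualized on the covariates
once; per-pair simple regressions then equal the full multiple-regression
coefficient by Frisch–Waugh–Lovell, with t and p computed at the full
n−k−2 degrees of freedom. Per-platform significance uses Bonferroni
α = 5×10⁻⁸/m features. Clumping is greedy: smallest-p unassigned SNP leads
a locus and absorbs same-chromosome SNPs within 1 Mb at dosage r² > 0.1.
The 1 Mb window and the use of squared dosage correlation as the LD measure
are this package's choices; an unbounded window is quadratic and
biologically unmotivated. Per-metabolite genetic variance is the 0-clamped
adjusted R² of the covariate-residualized feature on its lead dosages.

**Enrichment.** Functional classes are assigned by interval overlap
(1-based inclusive; BED converted on ingest) with priority exonic > UTR >
intronic > intergenic when intervals overlap, and genes within a ±10 kb
window. The permutation test draws same-sized SNP sets from the
non-associated background 1000 times; empirical p = (1+#{null ≥ obs})/1001
is floored at ~0.001 by the add-one rule, matching the convention of
reporting "P < 0.001" at 1000 permutations. The catalog Fisher test uses
the 2×2 table [[|mQTL∩trait|, |trait∖mQTL|], [|mQTL∩height|, |height∖mQTL|]]
with a one-sided (greater) alternative, height serving as the polygenic
reference profile; other table constructions are defensible, so this one is
pinned in configuration. Note that with identical trait and height
catalogs the one-sided exact p is ≈ 0.6, not 1 — the tail includes the
observed table.

**Colocalization.** Per-SNP evidence is Wakefield's log approximate Bayes
factor, 0.5·[log(V/(V+W)) + z²·W/(V+W)] with V = se². Effect-prior SD W is
0.15 for quantitative traits and 0.2 (log-odds) for case-control —
conventional defaults, as are the priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.
Posteriors over H0–H4 use the standard configuration sums
(H3 ∝ p1·p2·(L1·L2−L12), H4 ∝ p12·L12) evaluated entirely in log space;
negative H3 mass from float cancellation is clamped at zero. A brute-force
enumeration over all single- and two-SNP configurations is the test oracle
(agreement to 1e-9 for m ≤ 50). Single-causal-variant assumption only; no
SuSiE-style multi-causal extension.

**Mendelian randomization.** Instruments: exposure p < 5×10⁻⁸, greedy LD
pruning at r² < 0.01 by ascending p, outcome alleles aligned to the
exposure effect allele (β and EAF flipped when swapped, mismatches
dropped), palindromic SNPs dropped when EAF ∈ [0.42, 0.58]. Wald ratio
SE is first-order σ_Y/|β_X|. IVW is the precision-weighted mean with
fixed-effect SE (optional √(Q/df) inflation). Weighted median interpolates
the 50 % point of the weight-ordered ratios; modes maximize a Gaussian
kernel density (unweighted / inverse-variance-weighted) with bandwidth
φ·0.9·s·n^(−1/5), s from MAD/0.6745, φ = 1. Median/mode SEs come from a
seeded parametric bootstrap (1000 draws) that redraws β_X and β_Y.
Cochran's Q = Σw_j(θ̂_j − θ̂_IVW)² on n−1 df. MR-Egger, MR-PRESSO and
multivariable MR are out of scope.

**Prediction.** Per cytokine (covariate-residualized), 10 repeats of
2-fold CV with *nested* selection: SNPs at marginal p < 5×10⁻⁵ and
metabolites at Spearman p < 0.001 chosen inside each training fold only.
Elastic Net with mixing 0.5 and penalty path chosen by internal 3-fold CV;
predictors z-scored by training-fold statistics. Accuracy is Spearman rho
on the held-out half; the SNP-only and SNP+metabolite models share split
indices exactly, and their 20 paired rhos are compared by a paired
two-sided t-test with BH adjustment across cytokines. When neither model
selects any predictor on any split both score 0 and the comparison is
reported as t = 0, p = 1.

## Numerical and degenerate-input choices

* Missing dosages are mean-imputed per SNP at analysis time only, never
  persisted; missing feature values use pairwise-complete observations in
  correlation stages and per-feature complete cases in residualization.
* HWE filtering uses the exact conditional test on rounded genotype
  counts (Wigginton-style), checked against a rational-arithmetic
  enumeration oracle.
* Constant dosages/features are skipped with a log line wherever a
  statistic would be undefined (scan pairs, Spearman pairs, Shapiro).
* All generators and bootstraps accept integer seeds and are
  bit-reproducible; the pipeline manifest records the config hash and seed
  so deterministic outputs re-run identically.

## Problem sizes

Test-suite and acceptance-script simulations are desk-scale by design:
cohorts of 300–5 000 individuals, tens-to-hundreds of SNPs, 1–100
features, 150–300 Monte Carlo replicates for calibration checks. These
sizes give the binomial/KS tolerances asserted in the tests; they do not
probe 4-million-SNP-scale performance, which is explicitly out of scope.

## Known limitations

* The generator omits population structure, batch/seasonal effects,
  imputation uncertainty and X-chromosome dosage; recovery results bound
  estimator correctness under the model's own assumptions only.
* Real-data headline numbers (29 loci, PP4 = 0.94 for the arachidonic-acid
  /Crohn's locus, the −0.06…−0.07 MR effects, platform-specific
  gender-effect fractions) require the original cohort and external GWAS
  summary files and are not reproducible here; the pipeline reproduces the
  *procedures* and the printed multiple-testing thresholds exactly, and the
  causal-chain pattern qualitatively on synthetic data.
* Explained-variance estimates are in-sample and carry selection optimism
  (see above); cross-validated alternatives live in the prediction module.
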