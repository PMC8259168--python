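"""Config-driven end-to-end orchestration.

A single YAML config pins every stage threshold and the master seed; a run
writes per-stage TSV/JSON outputs plus a manifest (config hash, seed,
per-stage outputs, row counts and thresholds) that makes deterministic
re-runs reproducible bit-for-bit. The ``demo`` preset walks the full causal
chain on synthetic data: simulated metabolome with planted mQTLs ->
QC -> correlation -> explained variance -> mQTL scan/clumping -> enrichment
-> colocalization of an exposure metabolite with a disease trait ->
four-method Mendelian randomization -> Elastic Net prediction comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import FeatureMatrix
from . import simulate as sim
from . import io_core, preprocess, correlate, varexp, mqtl, enrich, coloc, mr, predict

log = logging.getLogger("metaboqtl")

__all__ = ["default_config", "run_pipeline", "REQUIRED_KEYS"]

#: every stage threshold must be present in the config (no silent defaults
#: at run time; `default_config` spells all of them out)
REQUIRED_KEYS = [
    "seed",
    "correlate.fdr_alpha",
    "varexp.metabolite_p",
    "varexp.other_p",
    "mqtl.alpha_gw",
    "mqtl.clump_r2",
    "mqtl.clump_window_bp",
    "mr.p_threshold",
    "mr.r2_threshold",
    "coloc.p1",
    "coloc.p2",
    "coloc.p12",
    "enrich.n_perm",
    "predict.n_repeats",
    "predict.k_folds",
    "predict.alpha_mix",
]


def default_config() -> dict:
    """Demo-scale configuration with every stated stage threshold pinned."""
    return {
        "seed": 20210706,
        "simulate": {
            "n_samples": 500,
            "blocks": [{"n_snps": 20, "maf_range": [0.1, 0.5], "rho": 0.8}
                       for _ in range(3)],
            "n_features": 30,
            "n_planted": 8,
            "variance_fraction_median": 0.081,
            "n_cytokines": 4,
            # a colocalization region needs a strong shared signal in both
            # traits; the MR instrument set carries the modest causal effect
            "gwas_coloc": {"scenario": "shared_causal", "m_snps": 100,
                           "n_exposure": 50000, "n_outcome": 50000,
                           "theta": 0.5, "n_causal": 1},
            # large-n instrument preset: keeps all four MR estimators
            # within ~0.02 of theta (see docs/methods.md)
            "gwas_mr": {"scenario": "shared_causal", "m_snps": 200,
                        "n_exposure": 200000, "n_outcome": 200000,
                        "theta": -0.07, "n_causal": 8},
        },
        "qc": {"pca_sd_threshold": 4, "maf_min": 0.05, "hwe_alpha": 1e-4},
        "correlate": {"fdr_alpha": 0.05},
        "varexp": {"metabolite_p": 0.001, "other_p": 0.05, "collinearity_r": 0.9},
        "mqtl": {"alpha_gw": 5e-8, "clump_r2": 0.1, "clump_window_bp": 1e6},
        "mr": {"p_threshold": 5e-8, "r2_threshold": 0.01},
        "coloc": {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
        "enrich": {"n_perm": 1000},
        "predict": {"n_repeats": 10, "k_folds": 2, "alpha_mix": 0.5,
                    "snp_p": 5e-5, "metab_p": 0.001, "max_cytokines": 2},
    }


def _get(config: dict, dotted: str):
    node = config
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            raise KeyError(f"config missing required key {dotted!r}")
        node = node[part]
    return node


def validate_config(config: dict) -> None:
    for key in REQUIRED_KEYS:
        _get(config, key)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _demo_annotation(g) -> pd.DataFrame:
    """Synthetic interval annotation covering the simulated chromosomes."""
    rows = []
    for chrom in g.snps["chrom"].astype(str).unique():
        pos = g.snps.loc[g.snps["chrom"].astype(str) == chrom, "pos"]
        span = int(pos.max())
        rows.append((chrom, 1, span // 4, "exonic"))
        rows.append((chrom, span // 4 + 1, span // 2, "3'UTR"))
        rows.append((chrom, span // 2 + 1, 3 * span // 4, "intronic"))
        rows.append((chrom, 1, span, f"gene:GENE{chrom}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage on freshly simulated data; return the manifest."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }

    def record(stage: str, path: Path | None, n_rows: int, **extra) -> None:
        manifest["stages"][stage] = {
            "output": str(path) if path else None, "n_rows": int(n_rows), **extra}

    # --- simulate ----------------------------------------------------------
    scfg = config["simulate"]
    g = sim.simulate_genotypes(scfg["n_samples"], scfg["blocks"],
                               seed=int(rng.integers(2 ** 31)))
    g = io_core.filter_variants(g, config["qc"]["maf_min"], config["qc"]["hwe_alpha"])
    cov = sim.simulate_covariates(g.n_samples, seed=int(rng.integers(2 ** 31)),
                                  samples=g.samples)
    frac_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    fractions = sim.paper_like_fractions(scfg["n_planted"], frac_rng,
                                         median=scfg["variance_fraction_median"])
    planted_snps = frac_rng.choice(g.snp_ids, size=scfg["n_planted"], replace=False)
    planted = [{"snp": s, "feature": f"met_{j:04d}", "variance_fraction": float(f)}
               for j, (s, f) in enumerate(zip(planted_snps, fractions))]
    metab, cov, ledger = sim.simulate_metabolome(
        g, scfg["n_features"], planted, covariates=cov,
        seed=int(rng.integers(2 ** 31)))
    mapping = [{"source": f"met_{j:04d}", "cytokine": f"cyt_{j % scfg['n_cytokines']:03d}",
                "beta": 0.5} for j in range(min(4, scfg["n_features"]))]
    cyto, _ = sim.simulate_immune(metab, g, mapping, noise_sd=1.0,
                                  seed=int(rng.integers(2 ** 31)),
                                  cytokine_ids=[f"cyt_{i:03d}"
                                                for i in range(scfg["n_cytokines"])])
    def make_pair(key: str):
        gcfg = scfg[key]
        return sim.simulate_gwas_pair(
            gcfg["scenario"], gcfg["m_snps"], gcfg["n_exposure"],
            gcfg["n_outcome"], gcfg["theta"], seed=int(rng.integers(2 ** 31)),
            n_causal=gcfg["n_causal"])

    cexpo, coutc, _coloc_ledger = make_pair("gwas_coloc")
    expo, outc, gwas_ledger = make_pair("gwas_mr")
    io_core.write_genotype_tsv(g, outdir / "genotypes.tsv")
    io_core.write_feature_matrix(metab, outdir / "metabolites.tsv")
    io_core.write_feature_matrix(cyto, outdir / "cytokines.tsv")
    cov.to_csv(outdir / "covariates.tsv", sep="\t")
    io_core.write_summary_stats(cexpo, outdir / "coloc_exposure.tsv")
    io_core.write_summary_stats(coutc, outdir / "coloc_outcome.tsv")
    io_core.write_summary_stats(expo, outdir / "gwas_exposure.tsv")
    io_core.write_summary_stats(outc, outdir / "gwas_outcome.tsv")
    record("simulate", outdir / "metabolites.tsv", metab.n_samples,
           n_snps=g.n_snps, n_features=scfg["n_features"])

    # --- qc ----------------------------------------------------------------
    logm = preprocess.log_transform(metab)
    kept, flagged, _scores = preprocess.pca_outliers(
        logm, config["qc"]["pca_sd_threshold"])
    shapiro = preprocess.normality_report(logm)
    logm = logm.subset_samples(kept)
    cyto = cyto.subset_samples(cyto.samples.intersection(kept))
    shapiro.to_csv(outdir / "qc_shapiro.tsv", sep="\t")
    record("qc", outdir / "qc_shapiro.tsv", len(shapiro),
           flagged_samples=list(map(str, flagged)))

    # --- correlate ---------------------------------------------------------
    assoc = correlate.adjusted_spearman_scan(logm, cyto, cov)
    assoc.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    record("correlate", outdir / "correlations.tsv", len(assoc),
           fdr_alpha=config["correlate"]["fdr_alpha"],
           n_significant=int((assoc["q"] < config["correlate"]["fdr_alpha"]).sum()))

    # --- varexp ------------------------------------------------------------
    ve_rows = []
    for cyt in cyto.features:
        res = varexp.explain_variance(
            cyto.values[cyt], logm, cov,
            p_threshold=config["varexp"]["metabolite_p"],
            collinearity_r=config["varexp"]["collinearity_r"], response_id=cyt)
        ve_rows.append({"response": cyt, "adj_r2": res.clamped_adj_r2,
                        "n_kept": len(res.kept_features), "n": res.n})
    ve = pd.DataFrame(ve_rows)
    ve.to_csv(outdir / "varexp.tsv", sep="\t", index=False)
    record("varexp", outdir / "varexp.tsv", len(ve))

    # --- mqtl --------------------------------------------------------------
    records = mqtl.qtl_scan(g, logm, cov)
    thresh = mqtl.bonferroni_threshold(config["mqtl"]["alpha_gw"],
                                       logm.values.shape[1])
    sig = records[records["p"] < config["mqtl"]["alpha_gw"]]
    loci = mqtl.clump_loci(sig, g, config["mqtl"]["clump_r2"],
                           config["mqtl"]["clump_window_bp"]) if len(sig) else []
    gv_rows = []
    for feat, frac in ledger.target_genetic_variance.items():
        leads = [l.lead for l in loci if feat in l.features]
        if leads:
            gv_rows.append({"feature": feat, "target": frac,
                            "adj_r2": mqtl.genetic_variance(
                                logm.values[feat], leads, g, cov)})
    records.to_csv(outdir / "mqtl_records.tsv", sep="\t", index=False)
    pd.DataFrame([{**asdict(l), "members": ",".join(l.members),
                   "features": ",".join(l.features)} for l in loci]
                 ).to_csv(outdir / "mqtl_loci.tsv", sep="\t", index=False)
    pd.DataFrame(gv_rows).to_csv(outdir / "genetic_variance.tsv", sep="\t", index=False)
    record("mqtl", outdir / "mqtl_records.tsv", len(records),
           bonferroni_threshold=thresh, n_significant=len(sig), n_loci=len(loci))

    # --- enrich ------------------------------------------------------------
    annotation = _demo_annotation(g)
    annotated = enrich.annotate_snps(g.snps, annotation)
    sig_snps = pd.Index(sorted(set(sig["snp"])))
    bg_snps = annotated.index.difference(sig_snps)
    if len(sig_snps) and len(bg_snps) > len(sig_snps):
        er = enrich.permutation_enrichment(
            annotated.loc[sig_snps, "class"], annotated.loc[bg_snps, "class"],
            n_perm=config["enrich"]["n_perm"], seed=int(rng.integers(2 ** 31)))
        er.table.to_csv(outdir / "enrichment.tsv", sep="\t")
        record("enrich", outdir / "enrichment.tsv", len(er.table),
               n_perm=config["enrich"]["n_perm"])
    else:
        record("enrich", None, 0, note="insufficient significant SNPs")

    # --- coloc -------------------------------------------------------------
    ccfg = config["coloc"]
    cres = coloc.coloc_summary_stats(cexpo, coutc, ccfg["p1"], ccfg["p2"], ccfg["p12"])
    with open(outdir / "coloc.json", "w") as fh:
        json.dump({"pp": cres.pp, "m": cres.m}, fh, indent=2)
    record("coloc", outdir / "coloc.json", cres.m, **{k: float(v)
                                                      for k, v in cres.pp.items()})

    # --- mr ----------------------------------------------------------------
    instruments = mr.harmonize_and_select(expo, outc,
                                          p_threshold=config["mr"]["p_threshold"],
                                          r2_threshold=config["mr"]["r2_threshold"])
    mres = mr.mr_all_methods(instruments, seed=int(rng.integers(2 ** 31)))
    q, qdf, qp = mr.cochran_q(instruments)
    mr_out = {m: asdict(r) for m, r in mres.items()}
    mr_out["cochran_q"] = {"Q": q, "df": qdf, "p": qp}
    with open(outdir / "mr.json", "w") as fh:
        json.dump(mr_out, fh, indent=2)
    instruments.to_csv(outdir / "mr_instruments.tsv", sep="\t")
    record("mr", outdir / "mr.json", len(instruments),
           estimates={m: r.estimate for m, r in mres.items()})

    # --- predict -----------------------------------------------------------
    pcfg = config["predict"]
    sub = cyto.values.columns[: pcfg.get("max_cytokines", 2)]
    evals = predict.cv_compare(
        g, metab.subset_samples(kept), FeatureMatrix(cyto.values[sub], "cytokine"),
        cov, n_repeats=pcfg["n_repeats"], k_folds=pcfg["k_folds"],
        alpha_mix=pcfg["alpha_mix"], seed=int(rng.integers(2 ** 31)),
        snp_p=pcfg["snp_p"], metab_p=pcfg["metab_p"])
    pred_rows = [{"cytokine": c, "t": e.t_stat, "p": e.p, "q": e.q, **e.mean_rho}
                 for c, e in evals.items()]
    pd.DataFrame(pred_rows).to_csv(outdir / "predict.tsv", sep="\t", index=False)
    record("predict", outdir / "predict.tsv", len(pred_rows))

    manifest["truth"] = {
        "planted_mqtls": [list(map(str, t)) for t in ledger.snp_effects],
        "gwas_scenario": gwas_ledger.scenario,
        "theta": gwas_ledger.causal_effect_theta,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    for stage, info in manifest["stages"].items():
        if info["output"] and not Path(info["output"]).exists():
            raise RuntimeError(f"stage {stage} output missing: {info['output']}")
    return manifest
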