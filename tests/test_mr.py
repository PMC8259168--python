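"""Mendelian randomization: harmonization rules, estimator algebra against
independent oracles, heterogeneity calibration and robustness to invalid
instruments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboqtl import mr, simulate as sim
from metaboqtl.datatypes import SummaryStats


def summary(df_dict, **kw):
    base = dict(chrom="1", n=50000)
    t = pd.DataFrame(df_dict)
    for k, v in base.items():
        if k not in t:
            t[k] = v
    if "pos" not in t:
        t["pos"] = np.arange(1, len(t) + 1) * 1000
    if "p" not in t:
        t["p"] = 2 * stats.norm.sf(np.abs(t["beta"] / t["se"]))
    return SummaryStats(t, **kw)


def instrument_table(wald, wald_se, beta_x=None):
    """Hand-built instrument table with prescribed ratios and ratio SEs."""
    bx = np.ones(len(wald)) if beta_x is None else np.asarray(beta_x, float)
    wald = np.asarray(wald, float)
    wald_se = np.asarray(wald_se, float)
    return pd.DataFrame({
        "beta_x": bx, "se_x": np.full(len(wald), 1e-6),
        "beta_y": wald * bx, "se_y": wald_se * np.abs(bx),
        "wald": wald, "wald_se": wald_se, "weight": 1.0 / wald_se ** 2,
    }, index=[f"rs{i}" for i in range(len(wald))])


class TestHarmonize:
    def base_pair(self):
        expo = summary({"snp": ["rs1", "rs2", "rs3"], "ea": "A", "oa": "G",
                        "eaf": [0.3, 0.3, 0.3], "beta": [0.2, 0.25, 0.3],
                        "se": 0.01})
        return expo

    def test_swapped_alleles_flip_outcome_beta(self):
        expo = self.base_pair()
        outc = summary({"snp": ["rs1", "rs2", "rs3"],
                        "ea": ["A", "G", "A"], "oa": ["G", "A", "G"],
                        "eaf": [0.3, 0.7, 0.3],
                        "beta": [0.05, -0.06, 0.07], "se": 0.01})
        tab = mr.harmonize_and_select(expo, outc, p_threshold=1e-4)
        assert tab.loc["rs2", "beta_y"] == pytest.approx(0.06)   # sign flipped
        assert tab.loc["rs1", "beta_y"] == pytest.approx(0.05)

    def test_palindromic_ambiguous_dropped(self):
        expo = summary({"snp": ["rs1", "rs2"], "ea": ["A", "A"], "oa": ["T", "T"],
                        "eaf": [0.5, 0.2], "beta": [0.2, 0.2], "se": 0.01})
        outc = summary({"snp": ["rs1", "rs2"], "ea": ["A", "A"], "oa": ["T", "T"],
                        "eaf": [0.5, 0.2], "beta": [0.1, 0.1], "se": 0.01})
        tab = mr.harmonize_and_select(expo, outc, p_threshold=1e-4)
        assert list(tab.index) == ["rs2"]     # eaf 0.5 in the window -> dropped

    def test_ld_prune_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        n = 1000
        base = rng.binomial(2, 0.3, n).astype(float)
        dosage = pd.DataFrame({"rs1": base, "rs2": base,                 # r2 = 1
                               "rs3": rng.binomial(2, 0.3, n).astype(float)},
                              index=pd.Index([f"S{i}" for i in range(n)]))
        snps = pd.DataFrame({"chrom": "1", "pos": [1, 2, 3], "ref": "A",
                             "alt": "G"}, index=dosage.columns)
        from metaboqtl.datatypes import GenotypeMatrix
        ld_ref = GenotypeMatrix(dosage, snps)
        expo = summary({"snp": ["rs1", "rs2", "rs3"], "ea": "A", "oa": "G",
                        "eaf": 0.3, "beta": [0.30, 0.25, 0.2], "se": 0.01})
        outc = summary({"snp": ["rs1", "rs2", "rs3"], "ea": "A", "oa": "G",
                        "eaf": 0.3, "beta": [0.03, 0.02, 0.02], "se": 0.01})
        tab = mr.harmonize_and_select(expo, outc, p_threshold=1e-4, ld_ref=ld_ref)
        assert set(tab.index) == {"rs1", "rs3"}   # rs2 pruned against rs1

    def test_empty_selection_reports_attrition(self):
        expo = self.base_pair()
        outc = summary({"snp": ["rs1", "rs2", "rs3"], "ea": "A", "oa": "G",
                        "eaf": 0.3, "beta": 0.1, "se": 0.01})
        with pytest.raises(ValueError, match="attrition"):
            mr.harmonize_and_select(expo, outc, p_threshold=1e-300)


class TestEstimators:
    def test_single_instrument_wald_ratio(self):
        tab = instrument_table([0.5], [0.1])
        res = mr.mr_estimate(tab, "ivw")
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_degenerate_consensus_all_methods(self):
        tab = instrument_table([0.7] * 5, [0.1, 0.2, 0.1, 0.3, 0.2])
        for method in mr.METHODS:
            res = mr.mr_estimate(tab, method, n_boot=50, seed=1)
            assert res.estimate == pytest.approx(0.7, abs=1e-9)
        q, df, p = mr.cochran_q(tab)
        assert q == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_ivw_equals_wls_through_origin(self, rng):
        """IVW must equal weighted least squares of betaY on betaX through
        the origin with weights 1/se_y^2."""
        bx = rng.uniform(0.1, 0.5, 3)
        wald = rng.uniform(-0.2, 0.2, 3)
        wald_se = rng.uniform(0.05, 0.2, 3)
        tab = instrument_table(wald, wald_se, beta_x=bx)
        res = mr.mr_estimate(tab, "ivw")
        import statsmodels.api as sm
        w = 1.0 / tab["se_y"] ** 2
        fit = sm.WLS(tab["beta_y"], tab[["beta_x"]], weights=w).fit()
        assert res.estimate == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_weighted_median_equal_weights_is_plain_median(self):
        wald = [0.1, 0.4, 0.2, 0.9, 0.3]
        tab = instrument_table(wald, [0.1] * 5)
        res = mr.mr_estimate(tab, "weighted_median", n_boot=50, seed=2)
        assert res.estimate == pytest.approx(np.median(wald), abs=1e-9)

    def test_allele_coding_invariance(self, rng):
        bx = rng.uniform(0.1, 0.5, 6)
        tab = instrument_table(rng.uniform(-0.3, 0.3, 6), rng.uniform(0.05, 0.2, 6),
                               beta_x=bx)
        flipped = tab.copy()
        flipped.loc["rs0", ["beta_x", "beta_y"]] *= -1     # same SNP, other allele
        for method in mr.METHODS:
            a = mr.mr_estimate(tab, method, n_boot=100, seed=3)
            b = mr.mr_estimate(flipped, method, n_boot=100, seed=3)
            assert a.estimate == pytest.approx(b.estimate, abs=1e-9)

    def test_too_few_instruments(self):
        tab = instrument_table([0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError, match="3"):
            mr.mr_estimate(tab, "weighted_median")


class TestCochranQ:
    def test_hand_example(self):
        tab = instrument_table([1.0, 2.0], [1.0, 1.0])
        q, df, p = mr.cochran_q(tab)
        assert q == pytest.approx(0.5)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.5, 1))

    def test_requires_two(self):
        with pytest.raises(ValueError):
            mr.cochran_q(instrument_table([1.0], [1.0]))

    def test_type_one_error_calibration(self):
        """Homogeneous true effect: Q rejects at ~5%."""
        rejections = 0
        n_rep = 200
        theta = -0.07
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            wald_se = rng.uniform(0.02, 0.05, 8)
            wald = theta + rng.standard_normal(8) * wald_se
            _, _, p = mr.cochran_q(instrument_table(wald, wald_se))
            rejections += int(p < 0.05)
        assert abs(rejections / n_rep - 0.05) < 0.04


class TestRecovery:
    def test_four_methods_recover_theta_large_n(self):
        e, o, _ = sim.simulate_gwas_pair("shared_causal", theta=-0.07, seed=7,
                                         **sim.MR_LARGE_N_PRESET)
        tab = mr.harmonize_and_select(e, o)
        assert len(tab) == 8
        for method, res in mr.mr_all_methods(tab, n_boot=300, seed=7).items():
            assert abs(res.estimate - (-0.07)) < 0.02, method

    def test_ivw_near_unbiased(self):
        ests = []
        for seed in range(60):
            e, o, _ = sim.simulate_gwas_pair(
                "shared_causal", m_snps=60, n_exposure=200000, n_outcome=200000,
                theta=-0.07, seed=seed, n_causal=8)
            tab = mr.harmonize_and_select(e, o)
            ests.append(mr.mr_estimate(tab, "ivw").estimate)
        assert abs(np.mean(ests) + 0.07) < 0.01

    def test_weighted_median_tolerates_invalid_instruments(self):
        """30% of instruments get a constant pleiotropic offset at high
        precision: the weighted median stays near theta while IVW absorbs
        the bias."""
        theta, offset = -0.07, 0.15
        rng = np.random.default_rng(17)
        n_inst = 10
        wald_se = np.full(n_inst, 0.01)
        wald = theta + rng.standard_normal(n_inst) * wald_se
        wald[:3] += offset                        # 3/10 invalid
        tab = instrument_table(wald, wald_se)
        wm = mr.mr_estimate(tab, "weighted_median", n_boot=200, seed=17)
        ivw = mr.mr_estimate(tab, "ivw")
        assert abs(wm.estimate - theta) < 0.02
        assert abs(ivw.estimate - theta) >= 0.03


def test_bootstrap_reproducible():
    tab = instrument_table([0.1, 0.15, 0.2, 0.05], [0.05, 0.08, 0.06, 0.09])
    a = mr.mr_estimate(tab, "weighted_mode", n_boot=200, seed=5)
    b = mr.mr_estimate(tab, "weighted_mode", n_boot=200, seed=5)
    assert (a.estimate, a.se) == (b.estimate, b.se)


def test_second_order_ratio_se_exceeds_first_order():
    e, o, _ = sim.simulate_gwas_pair("shared_causal", theta=-0.07, seed=21,
                                     **sim.MR_LARGE_N_PRESET)
    first = mr.harmonize_and_select(e, o)
    second = mr.harmonize_and_select(e, o, ratio_se="second_order")
    assert (second["wald_se"] >= first["wald_se"] - 1e-15).all()
    # exposure uncertainty is tiny at the large-n preset, so estimates agree
    a = mr.mr_estimate(first, "ivw").estimate
    b = mr.mr_estimate(second, "ivw").estimate
    assert a == pytest.approx(b, abs=5e-3)
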