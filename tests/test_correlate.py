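"""Adjusted Spearman scans, BH-FDR against the step-up definition, and
deterministic correlation clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from metaboqtl.datatypes import FeatureMatrix
from metaboqtl import correlate as co


def fm(arr, cols=None, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    idx = pd.Index([f"S{i}" for i in range(arr.shape[0])], name="sample")
    cols = cols or [f"{prefix}{j}" for j in range(arr.shape[1])]
    return FeatureMatrix(pd.DataFrame(arr, index=idx, columns=cols), "other")


def bh_stepup_oracle(p):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0, exclude_min=True),
                min_size=1, max_size=80))
def test_bh_matches_stepup_definition(pvec):
    np.testing.assert_allclose(co.bh_adjust(np.array(pvec)),
                               bh_stepup_oracle(pvec), atol=1e-12)


def test_monotone_transform_gives_rho_one(rng):
    a = fm(rng.standard_normal((60, 1)), prefix="a")
    b = fm(np.exp(3 * a.values.to_numpy()), prefix="b")    # strictly increasing
    out = co.adjusted_spearman_scan(a, b)
    assert out.loc[0, "rho"] == pytest.approx(1.0)


def test_adjusted_equals_plain_under_constant_covariate(rng):
    a = fm(rng.standard_normal((80, 3)), prefix="a")
    b = fm(rng.standard_normal((80, 2)), prefix="b")
    cov = pd.DataFrame({"const": np.ones(80)}, index=a.samples)
    # a constant covariate column is collinear with the intercept; adjusted
    # scan must then reduce to the plain scan
    plain = co.adjusted_spearman_scan(a, b)
    rho, p, _ = co.spearman_grid(a.values, b.values)
    np.testing.assert_allclose(plain["rho"], rho.ravel(), atol=1e-12)


def test_null_scan_rarely_discovers(rng):
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = fm(r.standard_normal((500, 100)), prefix="a")
        b = fm(r.standard_normal((500, 10)), prefix="b")
        out = co.adjusted_spearman_scan(a, b)
        hits += int((out["q"] < 0.05).sum() > 0)
    assert hits <= 1      # >= 9/10 null scans must be discovery-free


def test_planted_association_recovered(rng):
    n = 500
    x = rng.standard_normal(n)
    a = fm(x[:, None], prefix="a")
    # rho_true ~ 0.5 via shared-component construction
    y = x + rng.standard_normal(n) * np.sqrt(3)
    b = fm(np.column_stack([y] + [rng.standard_normal(n) for _ in range(9)]),
           prefix="b")
    cov = pd.DataFrame({"age": rng.uniform(20, 60, n)}, index=a.samples)
    out = co.adjusted_spearman_scan(a, b, cov)
    hit = out[(out.feature_a == "a0") & (out.feature_b == "b0")].iloc[0]
    assert abs(hit["rho"] - 0.5) < 0.1
    assert hit["q"] < 0.05


def test_short_pairs_reported_undefined(rng):
    a = fm(rng.standard_normal((8, 1)), prefix="a")
    b = fm(rng.standard_normal((8, 1)), prefix="b")
    out = co.adjusted_spearman_scan(a, b)
    assert out["p"].isna().all()
    assert (out["n_pairs"] == 8).all()


def test_q_never_below_p(rng):
    a = fm(rng.standard_normal((100, 8)), prefix="a")
    b = fm(rng.standard_normal((100, 5)), prefix="b")
    out = co.adjusted_spearman_scan(a, b)
    assert (out["q"] >= out["p"] - 1e-12).all()


class TestHostFactorScan:
    def test_null_factor_and_identical_factor(self, rng):
        n = 300
        vals = rng.standard_normal((n, 30))
        feats = fm(vals)
        factors = pd.DataFrame({
            "noise": rng.standard_normal(n),
            "self": vals[:, 0],
        }, index=feats.samples)
        assoc, summary = co.host_factor_scan(feats, factors)
        s = summary.set_index("factor")
        assert s.loc["noise", "fraction_significant"] < 0.05
        row = assoc[(assoc["factor"] == "self") & (assoc["feature"] == "f0")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["q"] < 1e-10

    def test_positive_only_effects_give_positive_fraction_one(self, rng):
        n = 400
        factor = rng.standard_normal(n)
        feats = fm(np.column_stack([factor + 0.5 * rng.standard_normal(n)
                                    for _ in range(5)]))
        factors = pd.DataFrame({"x": factor}, index=feats.samples)
        _, summary = co.host_factor_scan(feats, factors)
        assert summary.loc[0, "fraction_positive"] == 1.0


class TestClustering:
    def make_assoc(self, grid, rows=None, cols=None):
        rows = rows or [f"r{i}" for i in range(grid.shape[0])]
        cols = cols or [f"c{j}" for j in range(grid.shape[1])]
        recs = [(rows[i], cols[j], grid[i, j])
                for i in range(grid.shape[0]) for j in range(grid.shape[1])]
        return pd.DataFrame(recs, columns=["feature_a", "feature_b", "rho"])

    def test_anticorrelated_blocks_contiguous(self):
        grid = np.array([
            [1.0, 1.0, -1.0, -1.0],
            [-1.0, -1.0, 1.0, 1.0],
            [1.0, 1.0, -1.0, -1.0],
            [-1.0, -1.0, 1.0, 1.0],
        ])
        rows, _ = co.cluster_correlation_matrix(self.make_assoc(grid))
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos["r0"] - pos["r2"]) == 1
        assert abs(pos["r1"] - pos["r3"]) == 1

    def test_single_element_identity(self):
        rows, cols = co.cluster_correlation_matrix(self.make_assoc(np.array([[0.3]])))
        assert rows == ["r0"] and cols == ["c0"]

    def test_partition_invariant_under_row_permutation(self, rng):
        grid = np.vstack([np.tile([1.0, -1.0], (3, 5)),
                          np.tile([-1.0, 1.0], (3, 5))])[:, :5]
        assoc = self.make_assoc(grid)
        rows1, _ = co.cluster_correlation_matrix(assoc)
        perm = assoc.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rows2, _ = co.cluster_correlation_matrix(perm)
        # same two blocks, each contiguous, regardless of input order
        blocks1 = {frozenset(rows1[:3]), frozenset(rows1[3:])}
        blocks2 = {frozenset(rows2[:3]), frozenset(rows2[3:])}
        assert blocks1 == blocks2 == {frozenset({"r0", "r1", "r2"}),
                                      frozenset({"r3", "r4", "r5"})}

    def test_matches_scipy_on_tie_free_input(self, rng):
        grid = rng.standard_normal((7, 5))
        assoc = self.make_assoc(grid)
        rows, _ = co.cluster_correlation_matrix(assoc)
        Z = hierarchy.linkage(pdist(grid), method="complete")
        ours = {frozenset(c) for c in _cut_sets(rows, grid)}
        scip = {frozenset(f"r{i}" for i in np.where(labels == k)[0])
                for labels in [hierarchy.fcluster(Z, 2, criterion="maxclust")]
                for k in np.unique(labels)}
        assert scip <= ours


def _cut_sets(leaf_order, grid):
    """All contiguous prefixes/suffixes of the leaf order (supersets of any
    2-cluster cut of the same dendrogram)."""
    names = list(leaf_order)
    return [names[:k] for k in range(1, len(names))] + \
           [names[k:] for k in range(1, len(names))]
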