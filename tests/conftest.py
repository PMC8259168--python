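import numpy as np
import pandas as pd
import pytest

from metaboqtl import simulate as sim
from metaboqtl.datatypes import FeatureMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-sample cohort with 3 LD blocks and 10 metabolites, two of which
    carry planted mQTLs (8% and 20% of variance)."""
    g = sim.simulate_genotypes(
        600,
        [{"n_snps": 8, "maf_range": (0.1, 0.5), "rho": 0.7} for _ in range(3)],
        seed=11,
    )
    planted = [
        {"snp": "rs000002", "feature": "met_0001", "variance_fraction": 0.08},
        {"snp": "rs000010", "feature": "met_0004", "variance_fraction": 0.20},
    ]
    metab, cov, ledger = sim.simulate_metabolome(g, 10, planted, seed=12)
    return g, metab, cov, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def gaussian_features(rng):
    vals = pd.DataFrame(
        rng.standard_normal((200, 6)),
        index=pd.Index([f"S{i:03d}" for i in range(200)], name="sample"),
        columns=[f"f{j}" for j in range(6)],
    )
    return FeatureMatrix(vals, "other")
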