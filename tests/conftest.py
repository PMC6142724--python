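import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prsrank as pr

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """150 individuals x 120 SNPs plus a constructed extreme individual."""
    cfg = pr.SynthConfig(n_individuals=150, n_snps=120, seed=11)
    table, geno, pheno, focal = pr.generate_cohort(cfg)
    return cfg, table, geno, pheno, focal


@pytest.fixture(scope="session")
def medium_cohort():
    """600 x 400 cohort used by LD and bootstrap checks."""
    cfg = pr.SynthConfig(n_individuals=600, n_snps=400, n_blocks=80, seed=7)
    table, geno, pheno, focal = pr.generate_cohort(cfg)
    return cfg, table, geno, pheno, focal


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
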