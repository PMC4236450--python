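import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import popvar as pv

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-population cohort shared by read-only tests."""
    cfg = pv.SimConfig(
        n_populations=4,
        n_snps=3000,
        n_gwas_snps=400,
        n_rare=60,
        n_low_count_private=10,
        n_private=5,
        n_deletion_sites=80,
        seed=11,
    )
    return cfg, pv.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
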