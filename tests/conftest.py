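import numpy as np
import pytest

from nbdosage import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared across tests (25 samples, sparse markers)."""
    cfg = synthdata.SimConfig(
        n_samples=25, snps_per_chrom=150, genes_per_chrom=6, seed=11
    )
    truth, bundle = synthdata.simulate_cohort(cfg)
    return cfg, truth, bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
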