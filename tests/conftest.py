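import numpy as np
import pytest

from deepcombi import (
    GenotypeMatrix,
    PhenotypeVector,
    SimulationConfig,
    simulate_dataset,
)
from deepcombi.data import default_snp_meta


@pytest.fixture(scope="session")
def small_dataset():
    """A quick semi-synthetic dataset: 200 noise + 20 informative SNPs."""
    cfg = SimulationConfig(n_subjects=300, n_noise_snps=200, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_genotypes(rng):
    counts = rng.integers(0, 3, size=(30, 8))
    return GenotypeMatrix(counts, default_snp_meta(8))


@pytest.fixture()
def balanced_phenotypes():
    return PhenotypeVector(np.array([0, 1] * 15))
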