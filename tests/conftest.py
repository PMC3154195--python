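import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bnpp.datamodel import GenotypeDataset
from bnpp.priors import PriorSpec
from bnpp.scoring import HyperparameterSpec


@pytest.fixture
def default_priors() -> PriorSpec:
    return PriorSpec()


@pytest.fixture
def default_hyper() -> HyperparameterSpec:
    return HyperparameterSpec()


@pytest.fixture
def random_dataset_factory():
    """Factory for random ternary-genotype / binary-phenotype datasets."""

    def make(n: int = 50, n_snps: int = 6, seed: int = 0) -> GenotypeDataset:
        rng = np.random.default_rng(seed)
        return GenotypeDataset(
            genotypes=rng.integers(0, 3, size=(n, n_snps)),
            phenotype=rng.integers(0, 2, size=n),
            snp_ids=[f"S{i + 1}" for i in range(n_snps)],
        )

    return make
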