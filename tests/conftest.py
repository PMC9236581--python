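import numpy as np
import pytest

from genofp import (
    OwnerKey,
    PopulationSpec,
    derive_knowledge,
    generate_population,
)


@pytest.fixture(scope="session")
def key():
    return OwnerKey(b"test-owner-secret-key")


@pytest.fixture(scope="session")
def small_pop():
    """20 trios + 40 unrelated individuals, 60 SNPs, moderate LD."""
    spec = PopulationSpec(
        n_families=20, n_unrelated=40, n_snps=60,
        maf=0.25, ld_r=0.4, seed=7)
    return generate_population(spec)


@pytest.fixture(scope="session")
def small_knowledge(small_pop):
    db, fams = small_pop
    return derive_knowledge(db, fams)


@pytest.fixture(scope="session")
def medium_pop():
    """150 trios + 300 unrelated, 80 SNPs — for attack statistics."""
    spec = PopulationSpec(
        n_families=150, n_unrelated=300, n_snps=80,
        maf=0.25, ld_r=0.4, seed=11)
    return generate_population(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
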