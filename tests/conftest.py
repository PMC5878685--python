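import numpy as np
import pytest

from nickscan import (
    SonicationParams,
    build_mat_region,
    compute_five_prime_counts,
    simulate_library,
)


@pytest.fixture(scope="session")
def m_genome():
    return build_mat_region("M_donorless")


@pytest.fixture(scope="session")
def nickfree_genome():
    return build_mat_region("nick_free")


@pytest.fixture(scope="session")
def nicked_run(m_genome):
    """A moderate nicked library plus its 5' count profile (seed fixed)."""
    params = SonicationParams(n_molecules=30_000, imprint_fraction=0.3, seed=7)
    reads = simulate_library(m_genome, params)
    profile = compute_five_prime_counts(reads, m_genome)
    return reads, profile, params


@pytest.fixture(scope="session")
def nickfree_run(nickfree_genome):
    """A no-imprint (low-imprint mutant analog) library and profile."""
    params = SonicationParams(n_molecules=30_000, imprint_fraction=0.0, seed=11)
    reads = simulate_library(nickfree_genome, params)
    profile = compute_five_prime_counts(reads, nickfree_genome)
    return reads, profile, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
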