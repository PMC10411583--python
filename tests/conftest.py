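import numpy as np
import pytest

from yeastcohort import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group miniature cohort (one diploid, one triploid group)."""
    config = synthetic.CohortConfig(
        n_chromosomes=2,
        chrom_length_bp=100_000,
        n_genes=20,
        group_specs=(
            synthetic.GroupSpec("A", 4, 2, 0.10, 0.004),
            synthetic.GroupSpec("B", 3, 3, 0.05, 0.006),
        ),
        seed=1,
    )
    return synthetic.simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
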