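import numpy as np
import pytest

from netprog.cohort import (
    CohortConfig,
    example_planted_edges,
    generate_cohort,
    generate_patterns,
)


@pytest.fixture(scope="session")
def patterns95():
    return generate_patterns(95, 0.0, seed=1)


@pytest.fixture(scope="session")
def planted_edges(patterns95):
    pdrp, pdcp = patterns95
    return example_planted_edges(pdrp, pdcp, seed=1)


@pytest.fixture(scope="session")
def cohort(planted_edges):
    """Paper-scale longitudinal cohort with planted effects (seed 11)."""
    gains, losses = planted_edges
    return generate_cohort(
        CohortConfig.paper_longitudinal(
            planted_gains=gains, planted_losses=losses, seed=11
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast small-parcellation cohort for smoke-level checks."""
    return generate_cohort(CohortConfig(n_regions=20, n_hc=10, n_case=8, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
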