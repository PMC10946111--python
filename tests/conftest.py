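import numpy as np
import pytest

from pseudonet import CountTable, GroupedStudy, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_study(rng) -> GroupedStudy:
    """Two-group study, p=6, n=16, positive counts, no planted effect."""
    n, p = 16, 6
    counts = rng.poisson(50, size=(n, p)) + 1
    group = np.repeat([1, 2], n // 2)
    covariates = rng.normal(55, 10, size=(n, 1))
    return GroupedStudy(
        counts=CountTable(counts), group=group, covariates=covariates
    )


@pytest.fixture
def simulated_study():
    return simulate_dataset(SimConfig(p=10, n=40, delta1=0.1, delta2=0.2, seed=7))
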