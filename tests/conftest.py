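import numpy as np
import pytest

from hemirc import CohortSpec, RunConfig, WeightedNetwork, generate_cohort, run_pipeline


def random_network(n: int, density: float, rng, weight_low=0.1, weight_high=0.9):
    """Erdos-Renyi-style symmetric weighted network for property tests."""
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < density
    w = rng.uniform(weight_low, weight_high, len(iu)) * present
    m = np.zeros((n, n))
    m[iu, ju] = w
    m += m.T
    return WeightedNetwork(m, [f"n{i}" for i in range(n)], ["L"] * n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-effects synthetic cohort, small enough for fast tests."""
    return generate_cohort(CohortSpec(n_nc=10, n_bd=10, seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """One pipeline run on a small cohort, shared across tests."""
    cfg = RunConfig(
        cohort_spec=CohortSpec(n_nc=8, n_bd=8, seed=7), n_null=5, seed=7
    )
    return run_pipeline(cfg)
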