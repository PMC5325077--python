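import numpy as np
import pytest

from slicepattern import synthetic


@pytest.fixture
def rng():
    # function-scoped so each test's draws are independent of execution order
    return np.random.default_rng(12345)


def _random_distribution(rng, n_max=30):
    from slicepattern.profiles import to_distribution

    n = int(rng.integers(5, n_max + 1))
    values = rng.random(n) ** 2 + 1e-6
    return to_distribution(values)


@pytest.fixture(scope="session")
def random_distribution_factory():
    return _random_distribution


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 40-gene cohort shared by read/write and stats tests."""
    config = synthetic.CohortConfig(
        n_genes=40, slice_count_range=(10, 14), noise_sigma=0.1,
        qc_fail_rate=0.05, seed=7)
    embryos, truth = synthetic.generate_cohort(config)
    return config, embryos, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic sigma=0 cohort for exact recovery assertions."""
    config = synthetic.CohortConfig(
        n_genes=30, slice_count_range=(20, 24), noise_sigma=0.0,
        qc_fail_rate=0.0, seed=11)
    embryos, truth = synthetic.generate_cohort(config)
    return config, embryos, truth
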