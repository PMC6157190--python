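import numpy as np
import pandas as pd
import pytest

from comethnet.synthetic import SimulationConfig, SimulatedStudy, simulate_study


@pytest.fixture(scope="session")
def default_study() -> SimulatedStudy:
    """The default 6-module study with modules 2, 4, 6 rewired post-treatment."""
    return simulate_study(SimulationConfig(seed=11, rewired_modules=frozenset({2, 4, 6})))


@pytest.fixture(scope="session")
def small_study() -> SimulatedStudy:
    """A small 3-module study (one rewired) for fast pipeline tests."""
    return simulate_study(
        SimulationConfig(
            n_families=30,
            family_size=4,
            n_probes=150,
            module_sizes=(40, 35, 30),
            rewired_modules=frozenset({2}),
            seed=5,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_correlation(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """A valid correlation matrix from random data (for property checks)."""
    X = rng.standard_normal((n, 3 * n))
    c = np.corrcoef(X)
    ids = [f"p{i}" for i in range(n)]
    return pd.DataFrame(c, index=ids, columns=ids)
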