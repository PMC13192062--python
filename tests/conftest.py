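import numpy as np
import pandas as pd
import pytest

from boolimpl import synthetic as syn


@pytest.fixture(scope="session")
def network_cohort():
    """Planted-network benchmark cohort (logic blocks + background)."""
    cfg = syn.network_benchmark_config()
    matrix, truth = syn.simulate_cohort(cfg, seed=11)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def trio():
    """Default synthetic training trio with planted signature."""
    cfg = syn.SynthConfig()
    datasets, truths = syn.simulate_training_trio(cfg, seed=7)
    return cfg, datasets, truths


@pytest.fixture
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0], [3.5, 4.25], [0.0, -1.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
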