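import numpy as np
import pandas as pd
import pytest

from regenomics.simulate import SimulationConfig, simulate_timecourse


@pytest.fixture(scope="session")
def small_timecourse():
    """Two species, 5 planted clusters, fully conserved, low noise."""
    cfg = SimulationConfig(
        seed=101, n_families=80, conservation_rate=1.0, noise_sd=0.1
    )
    return cfg, simulate_timecourse(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts(rng):
    """Small count matrix with a planted composition shift in sample B."""
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.1, size=(100, 2)).astype(float) + 1.0,
        columns=["A", "B"],
    )
    counts.iloc[:20, 1] *= 2.0  # sample B doubles 20 genes
    return counts
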