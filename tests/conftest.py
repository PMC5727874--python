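import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vomeroseq.simulate import SimParams, simulate_dataset

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete synthetic study shared across test modules."""
    params = SimParams(seed=11, n_genes=400, n_hotspots=2,
                       hotspot_sizes=(30, 36), n_chromosomes=2)
    return simulate_dataset(params)


@pytest.fixture()
def two_group_counts():
    """500 genes, 4 vs 4 samples, planted LFC=2 at mean 200 and alpha=0.1."""
    rng = np.random.default_rng(5)
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "strain": ["A"] * 4 + ["B"] * 4,
        "sex": ["male", "female"] * 4,
        "replicate": [1, 1, 2, 2] * 2,
    })
    mu = np.where(np.arange(8) < 4, 800.0, 200.0)
    r = 1 / 0.1
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu), size=(500, 8)).astype(np.int64),
        index=[f"g{i}" for i in range(500)], columns=meta["sample_id"])
    return counts, meta
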