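import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cryoviromics import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_scenario():
    """Two-region scenario small enough for fast end-to-end tests."""
    return synthetic.default_scenario(
        seed=7,
        n_proteins_per_region=300,
        n_genomes_per_region=40,
        n_samples_per_region=3,
        genome_length=3000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return synthetic.generate_all(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def coverage_frame():
    """Hand-written coverage table spanning the presence-rule boundary."""
    return pd.DataFrame(
        {
            "genome_id": ["g1", "g1", "g2", "g2", "g3", "g3"],
            "sample_id": ["s1", "s2", "s1", "s2", "s1", "s2"],
            "genome_length": [10_000, 10_000, 20_000, 20_000, 5_000, 5_000],
            "breadth_1x": [0.80, 0.74, 0.75, 0.90, 0.0, 1.0],
            "read_count": [500, 500, 500, 1000, 0, 250],
        }
    )
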