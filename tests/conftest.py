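import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def hand_table():
    """Four regions x two age bands with round numbers for hand arithmetic.

    Pooled rates: band 0 -> 14/1000 = 0.014, band 1 -> 25/1000 = 0.025.
    Expected deaths: a1 6.4, a2 6.7, b1 17.0, b2 8.9 (sum 39 = observed sum).
    """
    rows = [
        ("A", "a1", 0, 100, 1), ("A", "a1", 1, 200, 4),
        ("A", "a2", 0, 300, 6), ("A", "a2", 1, 100, 1),
        ("B", "b1", 0, 500, 5), ("B", "b1", 1, 400, 12),
        ("B", "b2", 0, 100, 2), ("B", "b2", 1, 300, 8),
    ]
    return pd.DataFrame(
        rows, columns=["country_id", "region_id", "age_band", "population", "deaths"]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured synthetic dataset shared across tests."""
    from geostruct import SimulationConfig, generate_dataset

    config = SimulationConfig(
        n_countries=5,
        regions_per_country=(8, 15),
        target_gini=(0.1, 0.5),
        mean_region_pop=(2e5, 8e5),
        variance_structure_true=3,
        beta1_true=-2.7,
        beta2_true=1.3,
        sigma_v_true=0.36,
        seed=7,
    )
    table, truth = generate_dataset(config)
    return config, table, truth
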