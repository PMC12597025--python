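import numpy as np
import pandas as pd
import pytest

from gutdrift.community import CountTable

FAMILIES = [
    "Enterobacteriaceae",
    "Comamonadaceae",
    "Bacillaceae",
    "Xanthomonadaceae",
    "Pseudomonadaceae",
]


@pytest.fixture
def families():
    return list(FAMILIES)


@pytest.fixture
def small_table(families):
    """Three hosts x five families, plain integer counts."""
    data = pd.DataFrame(
        [
            [6, 2, 0, 1, 1],
            [2, 2, 4, 0, 2],
            [0, 0, 7, 3, 0],
        ],
        index=["h1", "h2", "h3"],
        columns=families,
        dtype=float,
    )
    return CountTable(data)


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "sample_id": ["h1", "h2", "h3"],
            "immigration_level": [169.0, 169.0, 16.9],
            "instar": [3, 3, 5],
            "plant_id": ["p1", "p2", "p1"],
            "lineage_id": ["l1", "l1", "l2"],
            "copy_number": [1000.0, 38.0, 500.0],
        }
    ).set_index("sample_id")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_count_table(rng, n_samples=8, n_taxa=5, high=50):
    """Random positive count table for property checks."""
    data = rng.integers(0, high, size=(n_samples, n_taxa)).astype(float)
    data[data.sum(axis=1) == 0, 0] = 1.0  # avoid empty samples
    return CountTable(
        pd.DataFrame(
            data,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
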