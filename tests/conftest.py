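import numpy as np
import pandas as pd
import pytest

from ddaffinity import MetacommunityMatrix, SiteAttributeTable, TraitTable


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))


@pytest.fixture
def small_matrix():
    """4 species x 4 sites, no all-zero rows/columns, mixed occupancy."""
    prab = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
            [0, 0, 1, 1],
        ]
    )
    return MetacommunityMatrix(
        ("spA", "spB", "spC", "spD"), ("s1", "s2", "s3", "s4"), prab
    )


@pytest.fixture
def small_traits():
    frame = pd.DataFrame(
        {
            "abundance": [1.2, 0.4, 2.5, 0.9],
            "body_size": [3.0, 2.0, 1.0, 4.0],
            "combs": ["none", "one", "two", "one"],
        },
        index=["spA", "spB", "spC", "spD"],
    )
    return TraitTable(frame, categorical=["combs"])


@pytest.fixture
def small_sites():
    frame = pd.DataFrame(
        {
            "altitude": [100.0, 450.0, 900.0, 1200.0],
            "ndvi": [0.7, 0.5, 0.4, 0.2],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SiteAttributeTable(frame)


def random_binary_matrix(rng, n_species, n_sites, density=0.45):
    """Random prab matrix guaranteed to have no all-zero rows or columns."""
    while True:
        prab = (rng.random((n_species, n_sites)) < density).astype(int)
        if prab.sum(axis=1).min() > 0 and prab.sum(axis=0).min() > 0 and 0 < prab.mean() < 1:
            return MetacommunityMatrix(
                tuple(f"sp{i}" for i in range(n_species)),
                tuple(f"s{j}" for j in range(n_sites)),
                prab,
            )
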