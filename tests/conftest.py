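import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `import oracles`

from pelagos import CountTable, SampleMetadata, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_table():
    """4 samples x 5 ASVs with assorted structure."""
    counts = pd.DataFrame(
        [[5, 0, 3, 0, 2],
         [1, 3, 0, 0, 6],
         [0, 2, 2, 1, 0],
         [4, 4, 4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d", "e"],
    )
    return CountTable(counts)


@pytest.fixture
def toy_metadata():
    df = pd.DataFrame(
        {
            "latitude": [-40.0, -10.0, 10.0, 40.0],
            "longitude": [180.0, 180.0, 180.0, 180.0],
            "depth": [20.0, 20.0, 200.0, 300.0],
            "size_fraction": ["FL_0.2_3"] * 4,
            "province": ["SANT", "SPSG", "PNEQ", "PSAG"],
            "temperature": [5.0, 25.0, 27.0, 4.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleMetadata(df)


def random_count_table(rng, n_samples, n_asvs, depth=200):
    """Random table with strictly positive row sums."""
    while True:
        p = rng.dirichlet(np.ones(n_asvs) * 0.6, size=n_samples)
        counts = np.vstack([rng.multinomial(depth, row) for row in p])
        if (counts.sum(axis=1) > 0).all():
            return CountTable(pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(n_samples)],
                columns=[f"ASV_{j + 1:04d}" for j in range(n_asvs)],
            ))


@pytest.fixture
def random_tree_factory():
    def make(n_taxa, seed):
        return simulate_tree(n_taxa, 1.0, 0.0, seed=seed)
    return make
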