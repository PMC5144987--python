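import numpy as np
import pandas as pd
import pytest

import microplast as mp


@pytest.fixture(scope="session")
def small_design():
    """4 genotypes x 2 replicates x 2 sexes x 3 flies = 48 samples."""
    return mp.generate_design(4, 2, 3, infected_fraction=0.5, seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """Null counts (no planted effects) on the small design."""
    truth = mp.generate_truth(
        30, {}, dispersion_range=(0.1, 0.3), n_genotypes=4, n_replicates=2, seed=102
    )
    counts, s_true = mp.simulate_counts(small_design, truth, seed=103)
    return counts, small_design, truth, s_true


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    counts, design, truth, _ = small_dataset
    sf = mp.size_factors(counts)
    return mp.normalize(counts, sf), design
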