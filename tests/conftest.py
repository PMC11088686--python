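import numpy as np
import pytest

import rangegap as rg


@pytest.fixture(scope="session")
def stack():
    """A 30x30, 3-layer autocorrelated landscape shared across tests."""
    spec = rg.LandscapeSpec(n_rows=30, n_cols=30, n_layers=3,
                            autocorrelation_range=4, seed=11)
    return rg.make_env_stack(spec)


@pytest.fixture(scope="session")
def pca_stack(stack):
    return rg.pca_reduce(stack, variance_target=0.95)


@pytest.fixture(scope="session")
def true_suit(stack):
    truth = rg.SpeciesTruth(niche_center=np.zeros(3),
                            niche_breadth=np.full(3, 0.5))
    return rg.make_true_suitability(stack, truth)


@pytest.fixture(scope="session")
def occurrences(stack, true_suit):
    df = rg.sample_occurrences(true_suit, stack.grid, 80, seed=21, species="spA")
    sets, _ = rg.clean_records(df, extent=stack.grid.extent)
    return sets["spA"]


@pytest.fixture(scope="session")
def basins(stack):
    return rg.make_basins(stack.grid, n_basins=9, seed=31)
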