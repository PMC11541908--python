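import warnings

import numpy as np
import pytest

import kelpfold as kf


@pytest.fixture(scope="session")
def default_truth():
    return kf.SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def default_map(default_truth):
    """Balanced contact map simulated from the default truth at depth 1e6."""
    m = kf.simulate_contact_map(default_truth, 1_000_000)
    return kf.ice_balance(kf.mask_low_coverage(m))


@pytest.fixture(scope="session")
def default_tracks(default_truth):
    return kf.simulate_feature_tracks(default_truth)


@pytest.fixture(scope="session")
def default_compartments(default_map, default_tracks):
    default_map.genome.gc = default_tracks.gc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kf.call_compartments(default_map, mode="cis")


@pytest.fixture
def toy_genome():
    """Two chromosomes, 10 bins each, 10 kb bins."""
    return kf.GenomeSpec([("c1", 100_000), ("c2", 100_000)], 10_000)


def uniform_matrix(genome, value=4.0, unit_weights=True):
    """Constant symmetric matrix with unit weights (balanced == counts)."""
    n = genome.n_bins
    m = kf.ContactMatrix(genome, np.full((n, n), float(value)))
    if unit_weights:
        m.weights = np.ones(n)
    return m


@pytest.fixture
def uniform_map(toy_genome):
    return uniform_matrix(toy_genome)
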