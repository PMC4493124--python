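import numpy as np
import pandas as pd
import pytest

from ibmgs import GeneticMap, GenotypeMatrix
from ibmgs.popsim import simulate_study


@pytest.fixture(scope="session")
def study_full():
    """Full-scale two-population study: 6611 dense markers, 1339 sparse."""
    return simulate_study(np.random.default_rng(123))


@pytest.fixture(scope="session")
def study_small():
    """Scaled-down study (600 dense / 120 sparse markers) for cheap checks."""
    return simulate_study(np.random.default_rng(123), n_markers_dense=600,
                          n_markers_sparse=120)


@pytest.fixture
def tiny_map():
    """Three markers on one chromosome, 10-cM gaps."""
    return GeneticMap(["a", "b", "c"], [1, 1, 1], [0.0, 10.0, 20.0],
                      [100_000, 200_000, 300_000])


@pytest.fixture
def toy_genotypes(tiny_map):
    return GenotypeMatrix(["l1", "l2", "l3", "l4"], tiny_map,
                          [[0, 0, 2], [0, 2, 2], [2, 2, 0], [2, 0, 0]])
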