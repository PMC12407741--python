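import numpy as np
import pytest

from gspbench import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small but fully structured cohort: 4 subjects, 24 regions, 60 frames."""
    return CohortConfig(n_subjects=4, n_regions=24, n_timepoints=60,
                        n_communities=3, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connected_sc(rng, R=12, density=0.4):
    """Random symmetric nonnegative connected weight matrix for oracle tests."""
    from scipy.sparse.csgraph import connected_components

    from gspbench import StructuralConnectome
    while True:
        A = np.zeros((R, R))
        iu = np.triu_indices(R, 1)
        mask = rng.random(len(iu[0])) < density
        A[iu] = np.where(mask, rng.random(len(iu[0])) + 0.1, 0.0)
        A = A + A.T
        if connected_components((A > 0).astype(int), directed=False)[0] == 1:
            return StructuralConnectome(A, "NFD", "group")
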