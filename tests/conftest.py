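import numpy as np
import pytest

from kinosim import (
    KinomeArray,
    PeptideReplicateSet,
    SpotMeasurement,
    build_repository,
    simulate_repository,
)


def make_array(values, array_id="A", background=0.0, peptide_ids=None):
    """Build a KinomeArray from an (m, l) matrix of background-corrected
    values, storing foreground = value + background per spot."""
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if peptide_ids is None:
        peptide_ids = [f"p{j + 1}" for j in range(m)]
    peptides = tuple(
        PeptideReplicateSet(
            pid, tuple(SpotMeasurement(float(v) + background, background) for v in row)
        )
        for pid, row in zip(peptide_ids, values)
    )
    return KinomeArray(array_id, peptides)


@pytest.fixture
def array_builder():
    return make_array


@pytest.fixture(scope="session")
def default_repository_arrays():
    """Full-size simulated repository: 48 arrays, 297 peptides, 9 replicates."""
    return simulate_repository(seed=20150432)


@pytest.fixture(scope="session")
def default_repository(default_repository_arrays):
    return build_repository(default_repository_arrays)


@pytest.fixture(scope="session")
def small_repository_arrays():
    """Small repository for fast unit tests."""
    return simulate_repository(n=6, m=40, l=9, seed=77)


@pytest.fixture(scope="session")
def small_repository(small_repository_arrays):
    return build_repository(small_repository_arrays)
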