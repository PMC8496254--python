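import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capmap import (GenotypeMatrix, SimConfig, call_matrix, phase_markers,
                    simulate_dataset, simulate_parent, simulate_s1_population)
from capmap.grouping import GroupingParams
from capmap.twopoint import twopoint_all

settings.register_profile(
    "capmap",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("capmap")


@pytest.fixture(scope="session")
def small_sim():
    """Three-chromosome S1 simulation with realistic noise (n=200)."""
    cfg = SimConfig(chrom_lengths_cM=(60.0, 90.0, 75.0), markers_per_chromosome=30,
                    n_individuals=200, seed=3)
    truth, counts = simulate_dataset(cfg)
    return truth, counts


@pytest.fixture(scope="session")
def called_small(small_sim):
    truth, counts = small_sim
    matrix, coverage, dropped = call_matrix(counts)
    return truth, matrix


@pytest.fixture(scope="session")
def phased_small(called_small):
    truth, matrix = called_small
    result = phase_markers(matrix, twopoint_all, GroupingParams())
    return truth, result


@pytest.fixture(scope="session")
def clean_chromosome():
    """One clean 100 cM chromosome: 50 markers, n=415, no noise, uniform phase."""
    cfg = SimConfig(chrom_lengths_cM=(100.0,), markers_per_chromosome=50,
                    n_individuals=415, seed=7, missing_rate=0.0, seq_error_rate=0.0)
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    matrix = truth.genotypes(phase=np.zeros(len(truth.metadata), dtype=np.int8))
    return truth, matrix


def random_matrix(rng, n_ind=30, n_markers=20, missing=0.1):
    """Small random genotype matrix for property tests."""
    calls = rng.choice([0, 1, 2], size=(n_ind, n_markers),
                       p=[0.25, 0.5, 0.25]).astype(np.int8)
    calls[rng.random((n_ind, n_markers)) < missing] = -1
    return GenotypeMatrix(
        calls,
        np.array([f"i{k:03d}" for k in range(n_ind)], dtype=object),
        np.array([f"m{k:03d}" for k in range(n_markers)], dtype=object),
    )
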