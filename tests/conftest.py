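"""Shared fixtures: small grids for unit tests, one session-scoped cohort at
the full study grid for recovery-style checks."""

import numpy as np
import pytest

from striocompart import synthetic_data as sd
from striocompart.parcellation import TargetCountMaps, compute_bias
from striocompart.pipeline import simulate_cohort

SMALL_SHAPE = (24, 30, 24)


@pytest.fixture(scope="session")
def small_spec():
    return sd.StriatumSpec(grid_shape=SMALL_SHAPE, rng_seed=11)


@pytest.fixture(scope="session")
def small_gt(small_spec):
    return sd.generate_striatum(small_spec)


@pytest.fixture(scope="session")
def default_gt():
    """Ground truth at the full study grid (40 x 50 x 40, 1.25 mm)."""
    return sd.generate_striatum(sd.StriatumSpec(rng_seed=0))


@pytest.fixture(scope="session")
def default_counts(default_gt):
    return sd.generate_counts(default_gt, sd.BaitRegionSet(), sd.CountModel(),
                              seed=0)


@pytest.fixture(scope="session")
def default_bias(default_counts):
    return compute_bias(default_counts)


@pytest.fixture(scope="session")
def cohort4():
    """Four subjects at the study grid, counts only (no BOLD)."""
    return simulate_cohort(4, 42, with_bold=False)


def toy_counts(s_values, m_values):
    """1 x n x 1 count maps with one bait per class ('S' and 'M')."""
    s = np.asarray(s_values, dtype=float).reshape(1, -1, 1)
    m = np.asarray(m_values, dtype=float).reshape(1, -1, 1)
    striatum = np.ones(s.shape, dtype=bool)
    return TargetCountMaps(counts={"S": s, "M": m},
                           favored={"S": "striosome", "M": "matrix"},
                           striatum_mask=striatum)


@pytest.fixture
def toy_counts_factory():
    return toy_counts
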