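"""Shared fixtures: small synthetic cities and hand-built cell tables."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from isonymica.isonymy import CellFrequencyTable, DistanceMatrix
from isonymica.synthetic_city import CityConfig, generate_city


@pytest.fixture(scope="session")
def small_city_config() -> CityConfig:
    return CityConfig(
        n_persons=2000,
        n_groups=3,
        surnames_per_group=20,
        zipf_exponent=0.8,
        endogamy=0.9,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_city(small_city_config) -> pd.DataFrame:
    return generate_city(small_city_config)


def make_cells(freq_dicts, mean_ses=None, nx=8, ny=8, scale=1000):
    """Build a CellFrequencyTable from {cell: {surname: freq}} by hand."""
    counts = {
        c: Counter({s: int(round(p * scale)) for s, p in f.items()})
        for c, f in freq_dicts.items()
    }
    return CellFrequencyTable(
        freqs={c: dict(f) for c, f in freq_dicts.items()},
        counts=counts,
        person_counts={c: scale // 2 for c in freq_dicts},
        mean_ses=dict(mean_ses or {}),
        nx=nx,
        ny=ny,
        extent=(0.0, 1.0, 0.0, 1.0),
        n_candidate_cells=nx * ny,
    )


def matrix_from_offdiag(values: np.ndarray) -> DistanceMatrix:
    """Symmetric DistanceMatrix whose upper off-diagonal holds ``values``."""
    k = len(values)
    n = int(round((1 + np.sqrt(1 + 8 * k)) / 2))
    assert n * (n - 1) // 2 == k, "values length must be a triangular number"
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    m += m.T
    return DistanceMatrix(cells=[(i, 0) for i in range(n)], matrix=m, metric="euclid")
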