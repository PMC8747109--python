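import numpy as np
import pytest

from mycopattern import (
    ColonizationGrid,
    ObservationID,
    compute_indices,
    preset,
    records_to_frame,
    simulate_dataset,
)
from dataclasses import replace


def make_grid(cells, rep=1, seg=1, fld=1):
    return ColonizationGrid(ObservationID(rep, seg, fld), np.asarray(cells, dtype=np.int8))


def random_grids(rng, n, p_occupied=0.25):
    """Random grids with iid cell codes; occupied cells get a random
    structure 1..6."""
    grids = []
    for i in range(n):
        occ = rng.random((10, 10)) < p_occupied
        codes = rng.integers(1, 7, size=(10, 10))
        grids.append(make_grid(np.where(occ, codes, 0), rep=1, seg=1, fld=i + 1))
    return grids


@pytest.fixture(scope="session")
def festuca_grids():
    """One full synthetic dataset (4x15x15 = 900 grids), seed 1."""
    return simulate_dataset(replace(preset("festuca_like"), seed=1))


@pytest.fixture(scope="session")
def festuca_frame(festuca_grids):
    return records_to_frame([compute_indices(g) for g in festuca_grids])
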