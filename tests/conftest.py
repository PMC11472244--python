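import numpy as np
import pytest

from hzmhc.data_model import BinaryGenotypeMatrix, IndividualRecord, ZoneCategory
from hzmhc.simulate import SimParams, build_transect, run_split_simulation


@pytest.fixture(scope="session")
def small_split_states():
    """Two species pools from a downsized forward simulation (N=60)."""
    params = SimParams(N=60, seed=42, split_gens=(1.0,), burn_in_gens=600)
    rng = np.random.default_rng(42)
    return run_split_simulation(params, rng)[1.0]


@pytest.fixture(scope="session")
def small_transect(small_split_states):
    a, b = small_split_states
    rng = np.random.default_rng(7)
    return build_transect(a, b, rng)


@pytest.fixture
def toy_matrix():
    return BinaryGenotypeMatrix(
        ["i1", "i2", "i3", "i4"],
        ["a", "b", "c", "d", "e"],
        np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 0, 1, 0, 0],
                [0, 1, 1, 1, 0],
                [0, 0, 0, 1, 1],
            ]
        ),
    )


@pytest.fixture
def toy_records():
    def rec(i, sp, loc, q, cat):
        return IndividualRecord(i, sp, loc, q_score=q, zone_category=ZoneCategory(cat))

    return [
        rec("i1", "sp1", "L1", 0.01, "near"),
        rec("i2", "sp1", "L1", 0.02, "far"),
        rec("i3", "sp2", "L2", 0.99, "near"),
        rec("i4", "sp2", "L2", 0.98, "far"),
    ]
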