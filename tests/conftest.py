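import numpy as np
import pytest
from hypothesis import settings

import ductpotts as dp
from ductpotts.testing import random_blob_state

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_state(rng):
    """A 20x20 state with a handful of random connected cells."""
    return random_blob_state(20, 20, n_cells=6, rng=rng)


@pytest.fixture(scope="session")
def desk_duct():
    """Initial duct at desk scale (300x300, 25 luminal cells)."""
    cfg = dp.preset("solid", size=300)
    return dp.build_initial_state(cfg, np.random.default_rng(0))


def random_focal_with_neighbor(state, rng):
    """A uniformly random in-range focal site plus a differing neighbor label."""
    h, w = state.lattice.labels.shape
    offs = state.adjacency.offsets
    for _ in range(10_000):
        i = int(rng.integers(h))
        j = int(rng.integers(w))
        a = state.lattice.label_at(i, j)
        labels = [state.lattice.label_at(i + int(dr), j + int(dc))
                  for dr, dc in offs]
        cands = [l for l in labels if l != a]
        if cands:
            return dp.Site(i, j), int(cands[int(rng.integers(len(cands)))])
    raise RuntimeError("uniform fixture: no heterologous neighbor found")
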