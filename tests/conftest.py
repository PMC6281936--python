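import numpy as np
import pytest

from lamella import ModelParams, Tissue


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tissue(cells, bonds=(), seed=0):
    """Build a tissue from (position, R) tuples and index-pair bonds."""
    t = Tissue(ModelParams(seed=seed))
    ids = []
    for pos, R in cells:
        ids.append(t.add_cell(np.asarray(pos, dtype=float), R=R))
    for a, b in bonds:
        t.add_bond(ids[a], ids[b])
    return t, ids


@pytest.fixture
def bonded_pair():
    """Two bonded unit cells stretched to separation 3 (rest length 2)."""
    return make_tissue([((0.0, 0.0, 0.0), 1.0), ((3.0, 0.0, 0.0), 1.0)], bonds=[(0, 1)])
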