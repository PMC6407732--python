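import numpy as np
import pytest

from gazepair import grid as grid_mod
from gazepair.data import GazeStream


@pytest.fixture(scope="session")
def grid():
    return grid_mod.build_grid()


def make_stream(t, x, y, participant="a", trial=0, valid=None):
    """Binocular stream with both eyes at the same (x, y) path."""
    t = np.asarray(t, dtype=float)
    x = np.broadcast_to(np.asarray(x, dtype=float), t.shape).copy()
    y = np.broadcast_to(np.asarray(y, dtype=float), t.shape).copy()
    if valid is None:
        valid = np.ones_like(t, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    return GazeStream(
        participant=participant,
        trial=trial,
        t=t,
        lx=x,
        ly=y,
        rx=x.copy(),
        ry=y.copy(),
        lvalid=valid,
        rvalid=valid.copy(),
    )


@pytest.fixture
def stream_factory():
    return make_stream
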