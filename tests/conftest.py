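import numpy as np
import pytest

from pvsmorph.config import RunConfig
from pvsmorph.grid import VolumeGrid
from pvsmorph.phantom import PhantomSpec, generate_volume


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_phantom():
    """A clean 5-tube phantom on the standard small grid, with truth."""
    spec = PhantomSpec(seed=3)
    vol, truth, roi = generate_volume(spec)
    return spec, vol, truth, roi


def make_tube_volume(shape=(40, 40, 40), radius=1.0, background=0.0,
                     contrast=100.0, direction=(0.0, 0.0, 1.0), length=None):
    """Analytic isotropic tube through the grid centre (helper for filter tests)."""
    shape = tuple(shape)
    center = (np.asarray(shape) - 1) / 2.0
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    rel = idx - center
    t = rel @ direction
    if length is not None:
        t = np.clip(t, -length / 2.0, length / 2.0)
    closest = center + t[:, None] * direction
    d2 = np.sum((idx - closest) ** 2, axis=1)
    data = background + contrast * np.exp(-d2 / (2.0 * radius ** 2))
    return VolumeGrid(data.reshape(shape), (1.0, 1.0, 1.0))
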