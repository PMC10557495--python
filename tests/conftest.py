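import warnings

import numpy as np
import pytest

from avtopo.config import PhantomConfig
from avtopo.phantom import make_phantom
from avtopo.topology import extract_topology

warnings.filterwarnings("ignore", category=UserWarning)

SMALL = PhantomConfig(depth=2, shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0), root_radius=3.5)


def straight_tube(shape=(15, 15, 40), radius=3.0, axis=2):
    """Axis-aligned cylinder mask (default along x)."""
    z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = (np.asarray(shape) - 1) / 2.0
    axes = [z - c[0], y - c[1], x - c[2]]
    cross = [a for i, a in enumerate(axes) if i != axis]
    return (cross[0] ** 2 + cross[1] ** 2) <= radius**2


@pytest.fixture(scope="session")
def tube_mask():
    return straight_tube()


@pytest.fixture(scope="session")
def y_mask():
    """Y-shaped tube: one stem splitting into two arms."""
    shape = (40, 40, 40)
    z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    stem = ((y - 20) ** 2 + (x - 20) ** 2 <= 9) & (z <= 20)
    p = np.stack([z, y, x], axis=-1).astype(float)

    def arm(direction):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        rel = p - np.array([20.0, 20.0, 20.0])
        along = rel @ d
        rad2 = (rel**2).sum(-1) - along**2
        return (rad2 <= 9) & (along >= 0) & (along <= 18)

    return stem | arm((1, 1, 0)) | arm((1, -1, 0))


@pytest.fixture(scope="session")
def small_phantom():
    """One 64mm-cube phantom with its extracted topology (shared across tests)."""
    vol, art, vein = make_phantom(SMALL, seed=0)
    graph, dmap = extract_topology(vol.mask, vol.spacing)
    return vol, art, vein, graph, dmap
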