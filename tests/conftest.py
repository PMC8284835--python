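import numpy as np
import pytest

from seedscape.landscape import BufferView
from seedscape.types import CommunityBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_block(abundance, patch_id="p0", dispersal=None, centre=(0.0, 0.0)):
    ab = np.asarray(abundance)
    s = ab.shape[1]
    if dispersal is None:
        dispersal = np.ones(s, dtype=bool)
    return CommunityBlock(
        patch_id=patch_id,
        abundance=ab,
        species_labels=tuple(f"sp{i}" for i in range(s)),
        dispersal=np.asarray(dispersal, dtype=bool),
        centre=centre,
    )


def full_view(grid, cell_size=10.0):
    """A BufferView covering an entire small grid (every cell a member)."""
    g = np.asarray(grid, dtype=np.int16)
    return BufferView(
        classes=g,
        mask=np.ones(g.shape, dtype=bool),
        cell_size=cell_size,
        centre=(0.0, 0.0),
        radius_m=0.0,
    )


def random_block(rng, max_species=4, max_plots=3, max_count=6):
    """A random small community with every plot non-empty."""
    s = int(rng.integers(1, max_species + 1))
    n = int(rng.integers(1, max_plots + 1))
    while True:
        ab = rng.integers(0, max_count + 1, size=(n, s))
        if (ab.sum(axis=1) > 0).all() and ab.sum() > 0:
            return make_block(ab)
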