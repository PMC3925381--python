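import numpy as np
import pytest

from eccpipe.io_formats import EnvStack, GridRaster


def grid(values, mask=None, cell_size=1000.0, origin=(0.0, 0.0), name="layer") -> GridRaster:
    """Build a GridRaster from nested lists; mask defaults to all-valid."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return GridRaster(values=values, mask=np.asarray(mask, bool),
                      cell_size=cell_size, origin=origin, name=name)


def stack_from(elevation, climate: dict, mask=None, island_id="test") -> EnvStack:
    """Build an EnvStack from value arrays sharing one geometry."""
    elev = grid(elevation, mask=mask, name="elevation")
    layers = {"elevation": elev}
    for name, vals in climate.items():
        layers[name] = grid(vals, mask=elev.mask, name=name)
    return EnvStack(layers=layers, island_id=island_id)


@pytest.fixture(scope="session")
def small_island():
    """A deterministic small synthetic island with default truth."""
    from eccpipe.synthetic_landscape import default_truth, make_island

    truth = default_truth()
    stack = make_island(seed=7, shape=(40, 50), truth=truth, island_id="small")
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
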