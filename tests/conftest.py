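import numpy as np
import pytest

from chelonia.landscape import (Landscape, NestingSite, PatchLocation,
                                generate_synthetic_landscape)


@pytest.fixture(scope="session")
def minimal_landscape():
    return generate_synthetic_landscape(1, "minimal")


@pytest.fixture(scope="session")
def channel_landscape():
    return generate_synthetic_landscape(1, "channel")


@pytest.fixture(scope="session")
def reference_landscape():
    return generate_synthetic_landscape(1, "reference")


def make_landscape(mask, cell=7.0, sites=None, patches=None, u=None, v=None,
                   bbox=(25.0, 65.0, -30.0, 10.0)):
    """Hand-built world from a 0/1 mask given as list of strings or array.

    String rows are listed north-first for readability; they are flipped
    so row 0 ends up at the southern edge.
    """
    if isinstance(mask[0], str):
        arr = np.array([[int(ch) for ch in row] for row in mask])[::-1]
    else:
        arr = np.asarray(mask)
    n_rows, n_cols = arr.shape
    if sites is None:
        sites = [NestingSite(1, "AAA", cell / 2, cell / 2, 1.0)]
    if patches is None:
        patches = [PatchLocation(1, cell * 1.5, cell / 2),
                   PatchLocation(2, cell * 2.5, cell / 2)]
    zero = np.zeros((n_rows, n_cols))
    return Landscape(
        n_cols=n_cols, n_rows=n_rows, cell_size_km=cell, bbox=bbox,
        cell_type=arr.astype(np.int8),
        current_u=zero.copy() if u is None else np.asarray(u, dtype=float),
        current_v=zero.copy() if v is None else np.asarray(v, dtype=float),
        nesting_sites=sites, feeding_patches=patches,
    )


@pytest.fixture
def open_ocean():
    """A 30x30 all-ocean world, one site in the SW, two patches."""
    n = 30
    mask = np.zeros((n, n), dtype=int)
    return make_landscape(
        mask,
        sites=[NestingSite(1, "AAA", 10.0, 10.0, 1.0)],
        patches=[PatchLocation(1, 150.0, 10.0), PatchLocation(2, 150.0, 150.0)],
    )
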