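import numpy as np
import pytest

from cellcyclekit import simulate as sim
from cellcyclekit.profiles import CONFOCAL, EPIFLUORESCENCE


@pytest.fixture(scope="session")
def epi():
    return EPIFLUORESCENCE


@pytest.fixture(scope="session")
def confocal():
    return CONFOCAL


@pytest.fixture(scope="session")
def small_tile(epi):
    """One rendered epifluorescence tile: 8 cells, 2 touching the border."""
    cells = sim.sample_cells(8, epi, rng_seed=1, border_fraction=0.25)
    return sim.render_tile(cells, epi, noise_sd=0.0, rng_seed=2)


@pytest.fixture(scope="session")
def noisy_tile(epi):
    cells = sim.sample_cells(6, epi, rng_seed=5)
    return sim.render_tile(cells, epi, noise_sd=30.0, rng_seed=6)


def make_sphere(radius: int, pad: int = 2) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = n // 2
    zz, yy, xx = np.ogrid[:n, :n, :n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


def make_ellipsoid(semi_zyx, pad: int = 2) -> np.ndarray:
    az, ay, ax = semi_zyx
    shape = tuple(2 * (int(np.ceil(s)) + pad) + 1 for s in (az, ay, ax))
    cz, cy, cx = (s // 2 for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
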