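import numpy as np
import pytest

from mifish.scheme import build_chr2_scheme


@pytest.fixture(scope="session")
def scheme():
    return build_chr2_scheme()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_grid_scene(channel="a488", n_dots=10, photons=20000.0,
                    shape=(24, 96, 96), background=100.0):
    """Scene with well-separated dots on a lateral grid (one channel)."""
    from mifish.simulate import SceneTruth, TrueDot

    dots = []
    cols = 5
    for i in range(n_dots):
        r, c = divmod(i, cols)
        x = (15 + 15 * c) * 130.0
        y = (20 + 30 * r) * 130.0
        z = (8 + 4 * (i % 3)) * 200.0
        dots.append(TrueDot(f"p{i}", 0, x, y, z, {channel: photons}))
    return SceneTruth("nuclei", shape, [], dots, background, 5.0)
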