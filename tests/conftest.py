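import numpy as np
import pytest

import elpsnakes as es


@pytest.fixture
def unit_circle():
    """CCW unit circle with 256 nodes, centered at the origin."""
    return es.make_initial_circle((0.0, 0.0), 1.0, 256)


@pytest.fixture(scope="session")
def disk_image():
    """Noise-free blurred disk phantom: radius 30 at (64, 64) in 128x128."""
    spec = es.PhantomSpec(
        shape="disk", size=(128, 128), center=(64.0, 64.0), radii=30.0,
        blur=2.0, noise=0.0,
    )
    return es.make_phantom(spec)


@pytest.fixture(scope="session")
def seg_params():
    """Parameter set that segments the disk phantom to sub-pixel accuracy."""
    return es.SnakeParams(w1=0.005, w2=1e-6, c0=0.0, lam=5000.0, sigma=1.0,
                          n_points=60)


def circle_fn(s):
    """Unit circle as a 1-periodic map, the standard smooth test curve."""
    return (np.cos(2 * np.pi * s), np.sin(2 * np.pi * s))
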