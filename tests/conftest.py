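import numpy as np
import pytest

from fuccitrack.tracking import Track


def gaussian_blob(shape, cx, cy, sigma=3.0, peak=200.0):
    """Noise-free Gaussian blob image, float."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def straight_track(n_steps, step_px, cell_id="C1", birth_frame=0):
    """Track moving +x by step_px per frame."""
    return Track(
        id=cell_id,
        birth_frame=birth_frame,
        positions=[(i * step_px, 0.0) for i in range(n_steps + 1)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_walk_track(rng, n_steps, cell_id="C1", step_scale=2.0):
    steps = rng.normal(scale=step_scale, size=(n_steps, 2))
    pos = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) + 100.0
    return Track(id=cell_id, birth_frame=0, positions=[tuple(p) for p in pos])
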