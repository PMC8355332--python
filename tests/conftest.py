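import numpy as np
import pytest


def disc_image(shape, centers, radius, value=1000.0):
    """Image with bright discs at the given (row, col) centers."""
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


def grid_centers(n, shape, margin=10, spacing=24):
    """Up to n non-overlapping disc centers on a regular grid."""
    out = []
    y = margin
    while y < shape[0] - margin and len(out) < n:
        x = margin
        while x < shape[1] - margin and len(out) < n:
            out.append((y, x))
            x += spacing
        y += spacing
    if len(out) < n:
        raise ValueError("image too small for requested disc count")
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
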