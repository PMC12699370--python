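import numpy as np
import pytest


@pytest.fixture
def circle_points():
    """Factory: dense CCW circle outline in pixel coordinates."""

    def make(radius=10.0, n=2048, centre=(0.0, 0.0), clockwise=False):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        if clockwise:
            t = t[::-1]
        return np.column_stack(
            [radius * np.cos(t) + centre[0], radius * np.sin(t) + centre[1]]
        )

    return make


@pytest.fixture
def ellipse_points():
    """Factory: dense CCW ellipse outline (semi-axes a, b)."""

    def make(a=10.0, b=5.0, n=2000):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([a * np.cos(t), b * np.sin(t)])

    return make


@pytest.fixture
def disc_image():
    """Factory: two-level disc image (foreground fg, background bg)."""

    def make(shape=(128, 128), centre=(64, 64), radius=40, fg=200.0, bg=10.0):
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.full(shape, bg, dtype=float)
        img[(rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2] = fg
        return img

    return make
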