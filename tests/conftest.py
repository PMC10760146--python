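import numpy as np
import pytest

import octlumen as ol


@pytest.fixture(scope="session")
def circle_spec():
    return ol.PhantomSpec(shape=ol.Circle(1.5), seed=42)


@pytest.fixture(scope="session")
def circle_frame(circle_spec):
    """A clean speckled circular phantom and its ground truth."""
    return ol.synth_frame(circle_spec)


@pytest.fixture(scope="session")
def circle_contour(circle_frame):
    frame, _ = circle_frame
    contour, diag = ol.segment_frame(frame)
    assert contour is not None, diag.reason
    return contour


class AnalyticContour:
    """Duck-typed closed contour with an exact parametric sampler."""

    closed = True

    def __init__(self, fn):
        self._fn = fn

    def sample(self, n):
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        return self.evaluate(t)

    def evaluate(self, t):
        return self._fn(np.asarray(t, dtype=float))


@pytest.fixture
def make_ellipse_contour():
    def _make(a, b, center=(0.0, 0.0), phase=0.0):
        cx, cy = center

        def fn(t):
            th = 2 * np.pi * t + phase
            return np.stack([cx + a * np.cos(th), cy + b * np.sin(th)], axis=-1)

        return AnalyticContour(fn)

    return _make


def random_knotset(rng, n=None, r_range=(1.0, 2.5)):
    """Valid anticlockwise KnotSet with random angles and radii."""
    n = n or int(rng.integers(8, 30))
    angles = np.sort(rng.uniform(0, 360, n))
    while np.any(np.diff(angles) <= 1e-6):
        angles = np.sort(rng.uniform(0, 360, n))
    radii = rng.uniform(*r_range, n)
    th = np.radians(angles)
    xy = np.column_stack([radii * np.cos(th), radii * np.sin(th)])
    return ol.KnotSet(xy=xy, angles_deg=angles)
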