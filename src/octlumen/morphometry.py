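"""Per-frame lumen morphometry: area and centroid-chord diameters.

Area is the shoelace sum over a dense uniform parameter sampling of the
closed contour.  Diameters are chords through the area centroid: for
each direction phi in [0, 180) the chord length is r(phi) + r(phi+180)
where r is the polar radius profile of the contour about its centroid.
This matches the usual convention in which an ellipse with semi-axes
(a, b) has d_max = 2a and d_min = 2b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing

__all__ = [
    "LumenMetrics",
    "contour_area",
    "centroid_diameters",
    "frame_metrics",
    "polygon_metrics",
    "polygon_diameters",
]


@dataclass(frozen=True)
class LumenMetrics:
    area: float  # mm^2
    d_min: float  # mm
    d_max: float  # mm
    d_mean: float  # mm
    centroid: tuple[float, float]  # mm
    n_samples: int

    def __post_init__(self) -> None:
        if not (self.area > 0):
            raise ValueError("area must be > 0")
        tol = 1e-9 * max(self.d_max, 1.0)
        if not (self.d_min - tol <= self.d_mean <= self.d_max + tol):
            raise ValueError("diameters must satisfy d_min <= d_mean <= d_max")


def _shoelace(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _centroid(xy: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple polygon (falls back to vertex mean)."""
    x, y = xy[:, 0], xy[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = float(np.sum((x + np.roll(x, -1)) * cross) / (6 * a))
    cy = float(np.sum((y + np.roll(y, -1)) * cross) / (6 * a))
    return cx, cy


def _polar_profile(xy: np.ndarray, center: tuple[float, float]):
    """Sorted (theta, r) profile of a closed polygon about ``center``.

    Warns if the polygon is not star-shaped about the center (the polar
    angle is then not injective and chords are approximate).
    Returns arrays padded for periodic interpolation.
    """
    d = xy - np.asarray(center)
    theta = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta, kind="stable")
    theta_s, r_s = theta[order], r[order]
    # Star-shape check: winding of the angle sequence along the contour
    # should advance monotonically (allowing the single wrap).
    dtheta = np.diff(theta)
    wraps = np.sum(np.abs(dtheta) > np.pi)
    backsteps = np.sum((dtheta < 0) & (np.abs(dtheta) <= np.pi))
    forward = np.sum((dtheta > 0) & (np.abs(dtheta) <= np.pi))
    if wraps > 1 or min(backsteps, forward) > 0.02 * len(theta):
        warnings.warn("contour is not star-shaped about its centroid; "
                      "diameters are approximate", stacklevel=3)
    theta_pad = np.concatenate([theta_s[-1:] - 2 * np.pi, theta_s, theta_s[:1] + 2 * np.pi])
    r_pad = np.concatenate([r_s[-1:], r_s, r_s[:1]])
    return theta_pad, r_pad


def polygon_diameters(
    xy: np.ndarray, angular_step_deg: float = 1.0
) -> tuple[float, float, float]:
    """(d_min, d_max, d_mean) of centroid chords of a closed polygon."""
    center = _centroid(xy)
    theta_pad, r_pad = _polar_profile(xy, center)
    phi = np.radians(np.arange(0.0, 180.0, angular_step_deg))
    r_fwd = np.interp(phi, theta_pad, r_pad)
    r_bwd = np.interp(phi + np.pi, theta_pad, r_pad)
    chords = r_fwd + r_bwd
    return float(chords.min()), float(chords.max()), float(chords.mean())


def contour_area(contour, n_samples: int = 720) -> float:
    """Shoelace area (mm^2) of the contour sampled at uniform parameters.

    Warns (and still returns the absolute shoelace value) if the
    sampled polygon self-intersects.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    xy = contour.sample(n_samples)
    if not LinearRing(xy).is_simple:
        warnings.warn("sampled contour polygon self-intersects; area is approximate",
                      stacklevel=2)
    return abs(_shoelace(xy))


def centroid_diameters(contour, angular_step_deg: float = 1.0,
                       n_samples: int = 3600) -> tuple[float, float, float]:
    """(d_min, d_max, d_mean) centroid chords of a closed contour."""
    if not contour.closed:
        raise ValueError("contour must be closed")
    xy = contour.sample(n_samples)
    return polygon_diameters(xy, angular_step_deg=angular_step_deg)


def frame_metrics(contour, n_area_samples: int = 720,
                  angular_step_deg: float = 1.0) -> LumenMetrics:
    """Bundle area (720-sample shoelace) and 1-degree centroid chords."""
    area = contour_area(contour, n_samples=n_area_samples)
    d_min, d_max, d_mean = centroid_diameters(contour, angular_step_deg=angular_step_deg)
    centroid = _centroid(contour.sample(n_area_samples))
    return LumenMetrics(area=area, d_min=d_min, d_max=d_max, d_mean=d_mean,
                        centroid=centroid, n_samples=n_area_samples)


def polygon_metrics(xy: np.ndarray, angular_step_deg: float = 1.0) -> LumenMetrics:
    """Metrics of an explicit closed polygon (e.g. a contour read from CSV)."""
    xy = np.asarray(xy, dtype=float)
    area = abs(_shoelace(xy))
    d_min, d_max, d_mean = polygon_diameters(xy, angular_step_deg=angular_step_deg)
    return LumenMetrics(area=area, d_min=d_min, d_max=d_max, d_mean=d_mean,
                        centroid=_centroid(xy), n_samples=len(xy))
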