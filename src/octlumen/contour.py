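"""Radial-domain knot selection and closed-spline lumen contour fitting.

Edge pixels are converted to polar coordinates about the catheter
center (angles anticlockwise from +x in physical y-up coordinates),
grouped into 30 evenly spaced 12-degree angular domains, and the
shortest ray in each sufficiently populated domain becomes a knot
point.  Domains with fewer than 6 edge points — typically guidewire
shadows or side-branch gaps — contribute nothing, and the closed
interpolating spline bridges them.  Two geometric filters then run:
knots closer than 0.25 mm to their cyclic neighbor are dropped, and
knots whose discrete (Menger) curvature exceeds 5 mm^-1 are removed
iteratively.  The surviving knots are joined anticlockwise by a closed
interpolating cubic B-spline (a NURBS with unit weights).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import interpolate

from .preprocess import EdgeMap, FrameImage, PreprocessConfig, preprocess_frame

__all__ = [
    "EdgePoint",
    "DomainBins",
    "KnotSet",
    "LumenContour",
    "SegmentationConfig",
    "SegmentationDiagnostics",
    "UnsegmentableFrame",
    "collect_edge_points",
    "bin_into_domains",
    "pick_knots",
    "enforce_spacing",
    "menger_curvature",
    "prune_curvature",
    "fit_closed_curve",
    "segment_frame",
]


class EdgePoint(NamedTuple):
    angle_deg: float  # [0, 360), anticlockwise from +x (physical y-up)
    radius_mm: float  # > 0, from catheter center
    source_pixel: tuple[int, int]  # (x, y) px


@dataclass(frozen=True)
class SegmentationConfig:
    """All knot-selection constants.

    Defaults follow the printed algorithm: 30 domains of 12 degrees, a
    minimum of 6 edge points per contributing domain, a 0.25 mm knot
    spacing floor, and a 5 mm^-1 curvature ceiling.
    """

    n_domains: int = 30
    domain_width_deg: float = 12.0
    min_edge_count: int = 6
    min_knot_spacing_mm: float = 0.25
    max_curvature_per_mm: float = 5.0
    center_mask_radius_mm: float = 0.4
    min_knots_for_fit: int = 4

    def __post_init__(self) -> None:
        if abs(self.n_domains * self.domain_width_deg - 360.0) > 1e-9:
            raise ValueError("n_domains * domain_width_deg must equal 360")
        for name in ("min_knot_spacing_mm", "max_curvature_per_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_edge_count < 1 or self.min_knots_for_fit < 4:
            raise ValueError("min_edge_count >= 1 and min_knots_for_fit >= 4 required")


@dataclass(frozen=True)
class DomainBins:
    """Edge points partitioned into half-open angular domains.

    Domain i covers [i * width, (i + 1) * width) degrees.
    """

    bins: tuple[tuple[EdgePoint, ...], ...]
    domain_width_deg: float

    @property
    def n_domains(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class KnotSet:
    """Anticlockwise-ordered knot points in mm relative to the center."""

    xy: np.ndarray  # (N, 2) mm
    angles_deg: np.ndarray  # (N,), strictly increasing in [0, 360)
    provenance: tuple[int, ...] = ()  # source domain index per knot, if known

    def __post_init__(self) -> None:
        if len(self.xy) != len(self.angles_deg):
            raise ValueError("xy and angles_deg must have equal length")
        if len(self.angles_deg) > 1 and np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("knot angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.xy)

    def subset(self, keep: Sequence[int]) -> "KnotSet":
        keep = list(keep)
        prov = tuple(self.provenance[i] for i in keep) if self.provenance else ()
        return KnotSet(xy=self.xy[keep], angles_deg=self.angles_deg[keep],
                       provenance=prov)


@dataclass(frozen=True)
class LumenContour:
    """Closed interpolating cubic spline through the knot points.

    Stored as a NURBS with unit weights: degree, control points, knot
    vector.  ``knot_points`` are the interpolated data points and
    ``knot_params`` their parameter values in [0, 1].
    """

    degree: int
    control_points: np.ndarray  # (M, 2) mm
    knot_vector: np.ndarray  # nondecreasing, length M + degree + 1
    weights: np.ndarray  # (M,), all ones
    knot_points: np.ndarray  # (N, 2) interpolated points
    knot_params: np.ndarray  # (N + 1,), includes the closing parameter 1.0
    closed: bool = True

    def _tck(self):
        return (self.knot_vector, [self.control_points[:, 0], self.control_points[:, 1]],
                self.degree)

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the curve at parameter(s) t in [0, 1] (periodic)."""
        t = np.mod(np.asarray(t, dtype=float), 1.0 + 1e-15)
        x, y = interpolate.splev(t, self._tck())
        return np.stack([x, y], axis=-1)

    def sample(self, n: int) -> np.ndarray:
        """n points at uniform parameter values in [0, 1)."""
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        return self.evaluate(t)


class UnsegmentableFrame(ValueError):
    """Raised when a frame yields too few knots for a closed fit."""


@dataclass
class SegmentationDiagnostics:
    n_edge_pixels: int = 0
    n_edge_points: int = 0
    n_knots_raw: int = 0
    n_knots_spaced: int = 0
    n_knots_final: int = 0
    curvature_floor_hit: bool = False
    unsegmentable: bool = False
    reason: str = ""


def collect_edge_points(
    edges: EdgeMap,
    center: tuple[float, float] | None = None,
    mm_per_px: float | None = None,
    mask_radius_mm: float = 0.4,
) -> list[EdgePoint]:
    """Convert edge pixels to polar edge points about the catheter center.

    Pixels within ``mask_radius_mm`` of the center are excluded: the
    catheter ring produces edges closer to the origin than the lumen
    border and would otherwise win the shortest-ray selection.
    Image y points down, so the physical (anticlockwise, y-up) angle
    uses the negated pixel-y offset.
    """
    cx, cy = center if center is not None else edges.catheter_center
    mpp = mm_per_px if mm_per_px is not None else edges.mm_per_px
    pix = edges.pixels()
    if len(pix) == 0:
        return []
    dx = (pix[:, 0] - cx) * mpp
    dy = (cy - pix[:, 1]) * mpp
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(dy, dx)) % 360.0
    keep = radius > mask_radius_mm
    return [
        EdgePoint(angle_deg=float(a), radius_mm=float(r),
                  source_pixel=(int(p[0]), int(p[1])))
        for a, r, p in zip(angle[keep], radius[keep], pix[keep])
    ]


def bin_into_domains(points: Sequence[EdgePoint],
                     config: SegmentationConfig) -> DomainBins:
    """Partition points into the half-open angular domains."""
    bins: list[list[EdgePoint]] = [[] for _ in range(config.n_domains)]
    for p in points:
        idx = int(p.angle_deg // config.domain_width_deg)
        if idx >= config.n_domains:  # guard against angle == 360 - eps rounding
            idx = config.n_domains - 1
        bins[idx].append(p)
    return DomainBins(bins=tuple(tuple(b) for b in bins),
                      domain_width_deg=config.domain_width_deg)


def pick_knots(bins: DomainBins, config: SegmentationConfig) -> KnotSet:
    """Shortest-ray knot per sufficiently populated domain.

    Domains with fewer than ``min_edge_count`` points emit nothing; ties
    in radius break toward the smallest angle.
    """
    angles: list[float] = []
    xy: list[tuple[float, float]] = []
    provenance: list[int] = []
    for i, bin_pts in enumerate(bins.bins):
        if len(bin_pts) < config.min_edge_count:
            continue
        best = min(bin_pts, key=lambda p: (p.radius_mm, p.angle_deg))
        a = math.radians(best.angle_deg)
        angles.append(best.angle_deg)
        xy.append((best.radius_mm * math.cos(a), best.radius_mm * math.sin(a)))
        provenance.append(i)
    return KnotSet(xy=np.array(xy, dtype=float).reshape(-1, 2),
                   angles_deg=np.array(angles, dtype=float),
                   provenance=tuple(provenance))


def enforce_spacing(knots: KnotSet, min_spacing_mm: float = 0.25) -> KnotSet:
    """Drop knots closer than ``min_spacing_mm`` to their cyclic neighbor.

    Traversal is anticlockwise from the first knot; of a violating
    consecutive pair the later knot is dropped, and passes repeat to a
    fixpoint including the wrap-around pair.  On exit every cyclically
    consecutive pair is at least ``min_spacing_mm`` apart (trivially so
    when fewer than two knots remain).
    """
    keep = list(range(len(knots)))
    changed = True
    while changed and len(keep) >= 2:
        changed = False
        n = len(keep)
        for j in range(n):
            a, b = keep[j], keep[(j + 1) % n]
            if a == b:
                break
            d = float(np.hypot(*(knots.xy[a] - knots.xy[b])))
            if d < min_spacing_mm:
                keep.remove(b)  # drop the later knot of the pair
                changed = True
                break
    return knots.subset(keep)


def menger_curvature(p1, p2, p3) -> float:
    """Menger (circumcircle) curvature of three points, in mm^-1.

    kappa = 4 * triangle_area / (|p1p2| * |p2p3| * |p1p3|); collinear
    triples return 0.  Coincident points are rejected.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    d12 = float(np.hypot(*(p2 - p1)))
    d23 = float(np.hypot(*(p3 - p2)))
    d13 = float(np.hypot(*(p3 - p1)))
    if min(d12, d23, d13) == 0.0:
        raise ValueError("menger_curvature requires three distinct points")
    v, w = p2 - p1, p3 - p1
    area2 = abs(v[0] * w[1] - v[1] * w[0])  # twice the triangle area
    return 2.0 * area2 / (d12 * d23 * d13)


def _all_curvatures(xy: np.ndarray) -> np.ndarray:
    n = len(xy)
    out = np.empty(n)
    for i in range(n):
        out[i] = menger_curvature(xy[(i - 1) % n], xy[i], xy[(i + 1) % n])
    return out


def prune_curvature(
    knots: KnotSet,
    max_curvature_per_mm: float = 5.0,
    min_knots: int = 4,
) -> tuple[KnotSet, bool]:
    """Iteratively remove the worst over-curved knot.

    Recomputes neighbor curvatures after every removal; stops when no
    knot exceeds ``max_curvature_per_mm`` or the count reaches
    ``min_knots`` (then the result is flagged by the returned bool).
    """
    if len(knots) < 3:
        raise ValueError("prune_curvature requires at least 3 knots")
    keep = list(range(len(knots)))
    while True:
        kappa = _all_curvatures(knots.xy[keep])
        worst = int(np.argmax(kappa))
        if kappa[worst] <= max_curvature_per_mm:
            return knots.subset(keep), False
        if len(keep) <= min_knots:
            return knots.subset(keep), True
        del keep[worst]


def fit_closed_curve(knots: KnotSet, min_knots_for_fit: int = 4) -> LumenContour:
    """Closed interpolating cubic spline through the knots, anticlockwise.

    The curve is a periodic B-spline (NURBS with all weights 1) that
    passes through every knot to machine precision, with chord-length
    parameterization rescaled to [0, 1].
    """
    if len(knots) < min_knots_for_fit:
        raise UnsegmentableFrame(
            f"{len(knots)} knots < {min_knots_for_fit} required for a closed fit")
    pts = np.vstack([knots.xy, knots.xy[:1]])  # explicit closure
    tck, u = interpolate.splprep([pts[:, 0], pts[:, 1]], per=True, s=0, k=3)
    knot_vector, coeffs, degree = tck
    control_points = np.column_stack([coeffs[0], coeffs[1]])
    return LumenContour(
        degree=degree,
        control_points=control_points,
        knot_vector=np.asarray(knot_vector),
        weights=np.ones(len(control_points)),
        knot_points=knots.xy.copy(),
        knot_params=np.asarray(u),
        closed=True,
    )


def segment_frame(
    frame: FrameImage,
    config: SegmentationConfig | None = None,
    pre_config: PreprocessConfig | None = None,
) -> tuple[LumenContour | None, SegmentationDiagnostics]:
    """Full per-frame pipeline from raw frame to closed lumen contour.

    Frames that cannot produce a closed fit return ``(None, diag)`` with
    ``diag.unsegmentable`` set — mirroring the clinical workflow where
    such frames are flagged for manual correction — never an exception.
    """
    config = config or SegmentationConfig()
    diag = SegmentationDiagnostics()
    edges = preprocess_frame(frame, pre_config)
    diag.n_edge_pixels = len(edges)
    points = collect_edge_points(edges, mask_radius_mm=config.center_mask_radius_mm)
    diag.n_edge_points = len(points)
    bins = bin_into_domains(points, config)
    knots = pick_knots(bins, config)
    diag.n_knots_raw = len(knots)
    if len(knots) < 3:
        diag.unsegmentable = True
        diag.reason = f"only {len(knots)} raw knots"
        return None, diag
    knots = enforce_spacing(knots, config.min_knot_spacing_mm)
    diag.n_knots_spaced = len(knots)
    if len(knots) < 3:
        diag.unsegmentable = True
        diag.reason = f"only {len(knots)} knots after spacing filter"
        return None, diag
    knots, floor_hit = prune_curvature(
        knots, config.max_curvature_per_mm, config.min_knots_for_fit)
    diag.curvature_floor_hit = floor_hit
    diag.n_knots_final = len(knots)
    try:
        contour = fit_closed_curve(knots, config.min_knots_for_fit)
    except UnsegmentableFrame as exc:
        diag.unsegmentable = True
        diag.reason = str(exc)
        return None, diag
    return contour, diag
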