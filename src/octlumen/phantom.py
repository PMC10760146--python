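"""Synthetic OCT-like cross-section phantoms with analytic lumen geometry.

Each phantom frame mimics the appearance of an intravascular OCT
cross-section: a dark, blood-cleared lumen surrounded by a bright
vessel-wall band, a bright imaging-catheter ring near the frame center,
optional dark guidewire-shadow wedges radiating outward from the
catheter, optional angular gaps in the wall where a side branch opens,
and multiplicative speckle noise.  The lumen boundary is a parametric
polar curve r(theta) whose area and centroid-chord diameters are known
analytically (or to quadrature accuracy), so segmentation output can be
scored against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphometry import polygon_diameters
from .preprocess import FrameImage

__all__ = [
    "Circle",
    "Ellipse",
    "FourierShape",
    "PhantomSpec",
    "GroundTruth",
    "synth_frame",
    "synth_pullback",
    "default_suite_specs",
]

# 8-bit intensity means chosen so the wall sits above and the lumen well
# below the fixed binarization threshold of 164.
LUMEN_MEAN = 30.0
WALL_MEAN = 220.0
RING_MEAN = 200.0
BACKGROUND_MEAN = 10.0
SHADOW_MEAN = 15.0
RING_HALF_WIDTH_MM = 0.03


@dataclass(frozen=True)
class Circle:
    """Circular lumen of radius ``r0`` mm."""

    r0: float

    def radius(self, theta: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(theta, dtype=float), self.r0)

    def area(self) -> float:
        return math.pi * self.r0**2


@dataclass(frozen=True)
class Ellipse:
    """Elliptical lumen with semi-axes ``a`` (x) and ``b`` (y) in mm."""

    a: float
    b: float

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return (self.a * self.b) / np.sqrt(
            (self.b * np.cos(theta)) ** 2 + (self.a * np.sin(theta)) ** 2
        )

    def area(self) -> float:
        return math.pi * self.a * self.b


@dataclass(frozen=True)
class FourierShape:
    """Circle of radius ``r0`` perturbed by cosine harmonics.

    ``harmonics`` is a tuple of ``(order, amplitude_mm, phase_rad)``;
    r(theta) = r0 + sum a_k cos(k*theta + phi_k).  The enclosed area has
    the closed form  A = pi * (r0**2 + sum a_k**2 / 2)  because the
    cross terms integrate to zero over a full turn.
    """

    r0: float
    harmonics: tuple[tuple[int, float, float], ...] = ()

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        r = np.full_like(theta, self.r0)
        for k, amp, phase in self.harmonics:
            r = r + amp * np.cos(k * theta + phase)
        return r

    def area(self) -> float:
        return math.pi * (self.r0**2 + 0.5 * sum(a**2 for _, a, _ in self.harmonics))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic frame.

    Angles are in degrees, anticlockwise from the +x axis in physical
    (y-up) coordinates; lengths are in mm unless suffixed ``_px``.
    """

    shape: Circle | Ellipse | FourierShape
    image_size: int = 512
    mm_per_px: float = 0.01
    catheter_center: tuple[float, float] | None = None  # (x, y) px; None = image center
    catheter_ring_radius: float = 0.25
    wall_thickness: float = 0.5
    shadow_wedges: tuple[tuple[float, float], ...] = ()  # (start deg, width deg)
    branch_sectors: tuple[tuple[float, float], ...] = ()
    speckle_scale: float = 0.3
    seed: int = 0

    def center_px(self) -> tuple[float, float]:
        if self.catheter_center is not None:
            return self.catheter_center
        c = (self.image_size - 1) / 2.0
        return (c, c)

    def validate(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("invalid spec: mm_per_px must be > 0")
        if self.image_size < 8:
            raise ValueError("invalid spec: image_size must be >= 8 px")
        theta = np.linspace(0.0, 2 * math.pi, 4096, endpoint=False)
        if np.any(self.shape.radius(theta) <= self.catheter_ring_radius):
            raise ValueError(
                "invalid spec: r(theta) must exceed catheter_ring_radius everywhere"
            )
        for name, sectors in (
            ("shadow_wedges", self.shadow_wedges),
            ("branch_sectors", self.branch_sectors),
        ):
            for start, width in sectors:
                if not (0 <= width < 360):
                    raise ValueError(f"invalid spec: {name} width must be in [0, 360)")
        if self.speckle_scale < 0:
            raise ValueError("invalid spec: speckle_scale must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic lumen geometry of one phantom frame."""

    theta_deg: np.ndarray  # dense sample angles
    r_mm: np.ndarray  # lumen radius at each angle
    area: float  # mm^2, A = 1/2 * integral r(theta)^2 dtheta
    d_min: float  # mm, centroid chords
    d_max: float
    d_mean: float

    def __post_init__(self) -> None:
        if not (self.area > 0):
            raise ValueError("GroundTruth.area must be > 0")
        tol = 1e-9 * max(self.d_max, 1.0)
        if not (self.d_min - tol <= self.d_mean <= self.d_max + tol):
            raise ValueError("GroundTruth diameters must satisfy d_min <= d_mean <= d_max")


def _sector_mask(theta_deg: np.ndarray, sectors) -> np.ndarray:
    """Boolean mask of angles lying inside any (start, width) sector."""
    mask = np.zeros(theta_deg.shape, dtype=bool)
    for start, width in sectors:
        mask |= np.mod(theta_deg - start, 360.0) < width
    return mask


def ground_truth(spec: PhantomSpec, n_samples: int = 3600) -> GroundTruth:
    theta = np.linspace(0.0, 2 * math.pi, n_samples, endpoint=False)
    r = spec.shape.radius(theta)
    area = spec.shape.area()
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    d_min, d_max, d_mean = polygon_diameters(xy, angular_step_deg=1.0)
    return GroundTruth(
        theta_deg=np.degrees(theta),
        r_mm=r,
        area=area,
        d_min=d_min,
        d_max=d_max,
        d_mean=d_mean,
    )


def synth_frame(spec: PhantomSpec) -> tuple[FrameImage, GroundTruth]:
    """Render one phantom frame and return it with its ground truth.

    Rendering is deterministic in ``spec.seed``: the same spec always
    produces a bit-identical pixel array.
    """
    spec.validate()
    n = spec.image_size
    cx, cy = spec.center_px()
    xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    dx = (xx - cx) * spec.mm_per_px
    dy = (cy - yy) * spec.mm_per_px  # image y points down; physical y points up
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    theta_deg = np.degrees(theta) % 360.0

    r_lumen = spec.shape.radius(theta)
    img = np.full((n, n), BACKGROUND_MEAN)
    img[dist < r_lumen] = LUMEN_MEAN
    wall = (dist >= r_lumen) & (dist < r_lumen + spec.wall_thickness)
    img[wall] = WALL_MEAN

    if spec.branch_sectors:
        gap = wall & _sector_mask(theta_deg, spec.branch_sectors)
        img[gap] = LUMEN_MEAN
    if spec.shadow_wedges:
        shadow = _sector_mask(theta_deg, spec.shadow_wedges) & (
            dist > spec.catheter_ring_radius + RING_HALF_WIDTH_MM
        )
        img[shadow] = SHADOW_MEAN

    ring = np.abs(dist - spec.catheter_ring_radius) <= RING_HALF_WIDTH_MM
    img[ring] = RING_MEAN

    if spec.speckle_scale > 0:
        rng = np.random.default_rng(spec.seed)
        s2 = spec.speckle_scale**2
        # Gamma with mean 1 and CV = speckle_scale, multiplicative.
        noise = rng.gamma(shape=1.0 / s2, scale=s2, size=img.shape)
        img = img * noise

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    frame = FrameImage(pixels=pixels, mm_per_px=spec.mm_per_px, catheter_center=(cx, cy))
    return frame, ground_truth(spec)


def _subseed(seed: int, i: int) -> int:
    """Deterministic per-frame seed derived from (seed, i)."""
    return int(np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0] % (2**31))


def synth_pullback(
    n_frames: int,
    spec_sequence,
    seed: int = 0,
) -> tuple[list[FrameImage], list[GroundTruth]]:
    """Render an ordered pullback stack.

    ``spec_sequence`` is either a sequence of :class:`PhantomSpec` (one
    per frame) or a callable ``f(i, n_frames) -> PhantomSpec``.  Frame
    ``i`` is rendered with a sub-seed derived deterministically from
    ``(seed, i)``, overriding the spec's own seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames: list[FrameImage] = []
    truths: list[GroundTruth] = []
    for i in range(n_frames):
        if callable(spec_sequence):
            spec = spec_sequence(i, n_frames)
        else:
            spec = spec_sequence[i]
        spec = dataclass_replace(spec, seed=_subseed(seed, i))
        frame, gt = synth_frame(spec)
        frames.append(frame)
        truths.append(gt)
    return frames, truths


def dataclass_replace(spec: PhantomSpec, **kw) -> PhantomSpec:
    import dataclasses

    return dataclasses.replace(spec, **kw)


def default_suite_specs(n_frames: int, seed: int = 0) -> list[PhantomSpec]:
    """The default validation suite: mixed lumen shapes with artifacts.

    Frames cycle through circles, ellipses, and Fourier-perturbed
    circles with effective radii in [1, 2.5] mm, speckle on, one
    guidewire-shadow wedge of at most 24 degrees per frame, and a
    side-branch wall gap of at most 20 degrees on every third frame.
    """
    specs: list[PhantomSpec] = []
    for i in range(n_frames):
        rng = np.random.default_rng(_subseed(seed, i))
        kind = i % 3
        if kind == 0:
            shape = Circle(r0=float(rng.uniform(1.0, 2.5)))
        elif kind == 1:
            a = float(rng.uniform(1.3, 2.5))
            b = float(rng.uniform(1.0, a))
            shape = Ellipse(a=a, b=b)
        else:
            r0 = float(rng.uniform(1.2, 2.2))
            harmonics = tuple(
                (int(k), float(rng.uniform(0.03, 0.06) * r0), float(rng.uniform(0, 2 * math.pi)))
                for k in (2, 3)
            )
            shape = FourierShape(r0=r0, harmonics=harmonics)
        wedges = ((float(rng.uniform(0, 360)), float(rng.uniform(8, 24))),)
        branches = ()
        if i % 3 == 2:
            branches = ((float(rng.uniform(0, 360)), float(rng.uniform(12, 20))),)
        specs.append(
            PhantomSpec(
                shape=shape,
                shadow_wedges=wedges,
                branch_sectors=branches,
                speckle_scale=0.3,
                seed=0,  # overridden per frame by synth_pullback
            )
        )
    return specs
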