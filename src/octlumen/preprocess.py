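"""Artifact-robust edge preprocessing for OCT cross-section frames.

The chain turns a raw frame into a thin binary edge map in a fixed
order: grayscale conversion, median speckle filtering, grayscale
morphological opening (erosion then dilation with a square structuring
element), fixed-threshold binarization, and Canny edge detection.
The fixed threshold of 164 separates the bright vessel-wall band from
the dark lumen on 8-bit frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

__all__ = [
    "FrameImage",
    "BinaryImage",
    "EdgeMap",
    "PreprocessConfig",
    "to_grayscale",
    "median_filter",
    "erode",
    "dilate",
    "binarize",
    "detect_edges",
    "preprocess_frame",
]

# ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    """All preprocessing constants.

    ``canny_low`` / ``canny_high`` are hysteresis thresholds expressed
    as fractions of the maximum gradient magnitude of the
    Gaussian-smoothed input.
    """

    median_kernel: int = 5
    morph_kernel: int = 5
    binarize_threshold: int = 164
    canny_sigma: float = 1.0
    canny_low: float = 0.2
    canny_high: float = 0.6

    def __post_init__(self) -> None:
        for name in ("median_kernel", "morph_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {k}")
        if not (0 <= self.binarize_threshold <= 255):
            raise ValueError("binarize_threshold must be in [0, 255]")
        if not (self.canny_low < self.canny_high):
            raise ValueError("canny_low must be < canny_high")


@dataclass(frozen=True)
class FrameImage:
    """A single-channel 8-bit frame with physical calibration."""

    pixels: np.ndarray  # (H, W) uint8
    mm_per_px: float
    catheter_center: tuple[float, float]  # (x, y) px

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("FrameImage.pixels must be a non-empty 2D array")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        cx, cy = self.catheter_center
        if not (0 <= cx < self.width and 0 <= cy < self.height):
            raise ValueError("catheter_center must lie inside the image")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray) -> "FrameImage":
        return FrameImage(pixels=pixels, mm_per_px=self.mm_per_px,
                          catheter_center=self.catheter_center)


@dataclass(frozen=True)
class BinaryImage:
    """A {0, 1} image sharing the frame's geometry."""

    pixels: np.ndarray  # (H, W) uint8 in {0, 1}
    mm_per_px: float
    catheter_center: tuple[float, float]

    def __post_init__(self) -> None:
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryImage pixels must be 0 or 1")


@dataclass(frozen=True)
class EdgeMap:
    """Edge pixels of a frame as a boolean mask plus geometry."""

    mask: np.ndarray  # (H, W) bool
    mm_per_px: float
    catheter_center: tuple[float, float]

    def pixels(self) -> np.ndarray:
        """Edge pixel coordinates as an (N, 2) array of (x, y), 0-based."""
        ys, xs = np.nonzero(self.mask)
        return np.column_stack([xs, ys])

    def __len__(self) -> int:
        return int(self.mask.sum())


def to_grayscale(
    image: np.ndarray,
    mm_per_px: float,
    catheter_center: tuple[float, float] | None = None,
) -> FrameImage:
    """Convert an RGB(A) or grayscale array into an 8-bit FrameImage.

    RGB conversion uses BT.601 luma weights with round-half-up;
    grayscale input passes through unchanged.  ``catheter_center``
    defaults to the image center.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        gray = image.astype(np.uint8)
    elif image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        gray = np.floor(rgb @ _LUMA + 0.5).astype(np.uint8)
    else:
        raise ValueError(f"unsupported channel layout: shape {image.shape}")
    if catheter_center is None:
        catheter_center = ((gray.shape[1] - 1) / 2.0, (gray.shape[0] - 1) / 2.0)
    return FrameImage(pixels=gray, mm_per_px=mm_per_px, catheter_center=catheter_center)


def _check_kernel(kernel: int, frame: FrameImage) -> None:
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel > min(frame.width, frame.height):
        raise ValueError("kernel larger than image")


def median_filter(frame: FrameImage, kernel: int = 5) -> FrameImage:
    """Median filter with a square kernel and reflect-padded borders."""
    _check_kernel(kernel, frame)
    out = ndimage.median_filter(frame.pixels, size=kernel, mode="reflect")
    return frame.with_pixels(out)


def erode(frame: FrameImage, kernel: int = 5) -> FrameImage:
    """Grayscale erosion: window minimum over a square structuring element."""
    _check_kernel(kernel, frame)
    out = ndimage.grey_erosion(frame.pixels, size=(kernel, kernel), mode="reflect")
    return frame.with_pixels(out)


def dilate(frame: FrameImage, kernel: int = 5) -> FrameImage:
    """Grayscale dilation: window maximum over a square structuring element."""
    _check_kernel(kernel, frame)
    out = ndimage.grey_dilation(frame.pixels, size=(kernel, kernel), mode="reflect")
    return frame.with_pixels(out)


def binarize(frame: FrameImage, threshold: int = 164) -> BinaryImage:
    """Fixed-threshold binarization: pixel >= threshold -> 1, else 0."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must be in [0, 255]")
    out = (frame.pixels >= threshold).astype(np.uint8)
    return BinaryImage(pixels=out, mm_per_px=frame.mm_per_px,
                       catheter_center=frame.catheter_center)


def detect_edges(binary: BinaryImage, config: PreprocessConfig | None = None) -> EdgeMap:
    """Canny edge detection on a binary image.

    Hysteresis thresholds are taken as ``canny_low``/``canny_high``
    fractions of the maximum Sobel gradient magnitude of the
    Gaussian-smoothed image, so on a {0, 1} input this reduces to clean
    boundary extraction.
    """
    config = config or PreprocessConfig()
    img = binary.pixels.astype(float)
    if img.max() == img.min():
        mask = np.zeros(img.shape, dtype=bool)
    else:
        smoothed = filters.gaussian(img, sigma=config.canny_sigma)
        gmax = float(filters.sobel(smoothed).max())
        mask = feature.canny(
            img,
            sigma=config.canny_sigma,
            low_threshold=config.canny_low * gmax,
            high_threshold=config.canny_high * gmax,
            use_quantiles=False,
        )
    return EdgeMap(mask=mask, mm_per_px=binary.mm_per_px,
                   catheter_center=binary.catheter_center)


def preprocess_frame(
    image: np.ndarray | FrameImage,
    config: PreprocessConfig | None = None,
    mm_per_px: float | None = None,
    catheter_center: tuple[float, float] | None = None,
) -> EdgeMap:
    """Run the full fixed-order chain from raw image to edge map.

    Order: grayscale -> median filter -> erode -> dilate -> binarize ->
    Canny.  ``image`` may be a raw array (then ``mm_per_px`` is
    required) or an existing :class:`FrameImage`.
    """
    config = config or PreprocessConfig()
    if isinstance(image, FrameImage):
        frame = image
    else:
        if mm_per_px is None:
            raise ValueError("mm_per_px is required for raw array input")
        frame = to_grayscale(image, mm_per_px=mm_per_px, catheter_center=catheter_center)
    frame = median_filter(frame, config.median_kernel)
    frame = erode(frame, config.morph_kernel)
    frame = dilate(frame, config.morph_kernel)
    binary = binarize(frame, config.binarize_threshold)
    return detect_edges(binary, config)
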