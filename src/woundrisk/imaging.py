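"""Wound-area quantification from photographs.

The pipeline mirrors the clinical image-processing protocol: extract the
saturation plane of the HSV color model and invert it (wound tissue is the
low-saturation, therefore high-intensity, region), smooth it with a number
of median-filter passes, then segment by seeded region growing from a
user-supplied point inside the wound.  A reference marker of known physical
size in the same frame calibrates pixel counts to cm^2, and two dated visits
give the area change rate that feeds the Technical Risk engine.

Coordinates are 0-based (row, column); masks keep the image orientation.
"""

from __future__ import annotations

import datetime as _dt
from collections import deque
from dataclasses import dataclass
from os import PathLike

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv

__all__ = [
    "WoundImage",
    "ReferenceMarker",
    "SegmentationResult",
    "AreaChange",
    "load_image",
    "preprocess",
    "region_grow",
    "calibrate",
    "area_change_rate",
    "measure_wound",
]


@dataclass
class WoundImage:
    """One visit's RGB photograph with its capture date."""

    pixels: np.ndarray  # (H, W, 3) uint8/uint16 or float in [0, 1]
    capture_date: _dt.date
    path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected an RGB raster of shape (H, W, 3), got {px.shape}"
            )
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"image too small: {px.shape[:2]}, need >= 64x64")
        self.pixels = px


@dataclass
class ReferenceMarker:
    """Reference element of known physical size present in the frame."""

    physical_area_cm2: float
    seed: tuple[int, int] | None = None
    pixel_area: int = 0

    def __post_init__(self) -> None:
        if self.physical_area_cm2 <= 0:
            raise ValueError("marker physical area must be positive")


@dataclass
class SegmentationResult:
    mask: np.ndarray  # bool (H, W)
    pixel_area: int
    physical_area_cm2: float
    seed: tuple[int, int]
    sensitivity: float


@dataclass
class AreaChange:
    """Signed wound-area change between two dated visits.

    ``rate`` is in cm^2/day; ``rate_pct`` in percent of the reference
    (earlier) area per day.  Negative values mean healing.
    """

    area_ref_cm2: float
    area_now_cm2: float
    days_elapsed: float

    def __post_init__(self) -> None:
        if self.days_elapsed <= 0:
            raise ValueError("days_elapsed must be positive")
        if self.area_ref_cm2 <= 0:
            raise ValueError("reference area must be positive")

    @property
    def rate(self) -> float:
        return (self.area_now_cm2 - self.area_ref_cm2) / self.days_elapsed

    @property
    def rate_pct(self) -> float:
        return 100.0 * self.rate / self.area_ref_cm2


def load_image(path: str | PathLike, capture_date: _dt.date) -> WoundImage:
    """Read a PNG/JPEG/TIFF photograph (honoring orientation metadata)."""
    pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return WoundImage(pixels=pixels, capture_date=capture_date, path=str(path))


def _as_float_rgb(pixels: np.ndarray) -> np.ndarray:
    if pixels.dtype == np.uint8:
        return pixels / 255.0
    if pixels.dtype == np.uint16:
        return pixels / 65535.0
    pixels = pixels.astype(float)
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("float images must be scaled to [0, 1]")
    return pixels


def preprocess(image: WoundImage | np.ndarray, n_filters: int = 5) -> np.ndarray:
    """Inverted saturation plane after ``n_filters`` median-smoothing passes.

    Returns a float raster in [0, 1] where low-saturation (wound) tissue is
    bright.  ``n_filters=0`` returns the inverted saturation unchanged.
    """
    pixels = image.pixels if isinstance(image, WoundImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(f"expected RGB input of shape (H, W, 3), got {pixels.shape}")
    if n_filters < 0:
        raise ValueError("n_filters must be >= 0")
    channel = 1.0 - rgb2hsv(_as_float_rgb(pixels))[:, :, 1]
    for _ in range(n_filters):
        channel = median_filter(channel, size=3, mode="nearest")
    return channel


def region_grow(
    channel: np.ndarray, seed: tuple[int, int], sensitivity: float
) -> np.ndarray:
    """Seeded region growing with a running-mean criterion.

    Starting from ``seed``, 4-connected neighbors are absorbed while their
    intensity deviates from the running mean of the region grown so far by
    at most ``sensitivity``; the frontier is processed FIFO, which makes the
    result deterministic.  Returns a boolean mask containing the seed.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("region_grow expects a single-channel 2-D raster")
    rows, cols = channel.shape
    r0, c0 = seed
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"seed {seed} outside raster of shape {channel.shape}")
    if sensitivity < 0:
        raise ValueError("sensitivity must be nonnegative")

    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0, c0] = True
    total = channel[r0, c0]
    count = 1
    frontier: deque[tuple[int, int]] = deque([(r0, c0)])
    while frontier:
        r, c = frontier.popleft()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < rows and 0 <= nc < cols and not mask[nr, nc]:
                # 1e-12 guard: the running mean accumulates float round-off,
                # which must not exclude pixels identical to the region
                if abs(channel[nr, nc] - total / count) <= sensitivity + 1e-12:
                    mask[nr, nc] = True
                    total += channel[nr, nc]
                    count += 1
                    frontier.append((nr, nc))
    return mask


def calibrate(marker: ReferenceMarker) -> float:
    """Scale in cm^2 per pixel from the detected reference marker."""
    if marker.pixel_area <= 0:
        raise ValueError("marker pixel area must be positive; detect the marker first")
    return marker.physical_area_cm2 / marker.pixel_area


def area_change_rate(
    before: SegmentationResult,
    before_date: _dt.date,
    after: SegmentationResult,
    after_date: _dt.date,
) -> AreaChange:
    """Area change rate between two dated segmentations (after minus before)."""
    days = (after_date - before_date).days
    if days <= 0:
        raise ValueError(
            f"after date {after_date} must be strictly later than before date {before_date}"
        )
    return AreaChange(
        area_ref_cm2=before.physical_area_cm2,
        area_now_cm2=after.physical_area_cm2,
        days_elapsed=float(days),
    )


def measure_wound(
    image: WoundImage,
    wound_seed: tuple[int, int],
    marker: ReferenceMarker,
    sensitivity: float = 0.15,
    n_filters: int = 5,
) -> SegmentationResult:
    """Segment the wound and the reference marker, and calibrate the area.

    Both regions are grown on the same preprocessed channel.  The marker
    needs its own seed (``marker.seed``); its pixel count is stored back on
    the marker object.
    """
    if marker.seed is None:
        raise ValueError("marker.seed is required to locate the reference element")
    channel = preprocess(image, n_filters=n_filters)
    wound_mask = region_grow(channel, wound_seed, sensitivity)
    marker_mask = region_grow(channel, marker.seed, sensitivity)
    if (wound_mask & marker_mask).any():
        raise ValueError(
            "wound and marker regions overlap; check seeds and sensitivity"
        )
    marker.pixel_area = int(marker_mask.sum())
    scale = calibrate(marker)
    pixel_area = int(wound_mask.sum())
    return SegmentationResult(
        mask=wound_mask,
        pixel_area=pixel_area,
        physical_area_cm2=pixel_area * scale,
        seed=tuple(wound_seed),
        sensitivity=sensitivity,
    )
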