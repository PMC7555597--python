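"""Deterministic synthetic wound photographs with known ground truth.

The generator emulates the inputs the measurement pipeline expects: an
elliptical wound of distinctly low saturation (pale granulation tissue) on a
more saturated skin-tone background, a saturated red reference square of
known physical size, and optional Gaussian pixel noise.  Because the
preprocessing step inverts the saturation plane, the wound is the bright
region of the preprocessed channel by construction.

Every image is reproducible from its spec's seed, and analytic areas
(pi*a*b for the ellipse, side^2 for the marker) are returned alongside the
rasterized ground-truth masks.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .imaging import AreaChange, WoundImage

__all__ = ["SyntheticWoundSpec", "SyntheticTruth", "generate_wound_image", "generate_case_pair"]

# Default palette (RGB, 0-255).  Saturation S = 1 - min/max:
#   skin   (198, 144, 114) -> S ~ 0.42  (inverted ~ 0.58)
#   wound  (233, 213, 205) -> S ~ 0.12  (inverted ~ 0.88)
#   marker (190, 32, 38)   -> S ~ 0.83  (inverted ~ 0.17)
SKIN_RGB = (198, 144, 114)
WOUND_RGB = (233, 213, 205)
MARKER_RGB = (190, 32, 38)


@dataclass(frozen=True)
class SyntheticWoundSpec:
    """Parameters of one synthetic wound photograph."""

    shape: tuple[int, int] = (256, 256)
    wound_center: tuple[float, float] = (140.0, 128.0)
    wound_semi_axes: tuple[float, float] = (45.0, 30.0)
    marker_origin: tuple[int, int] = (12, 12)  # top-left corner (row, col)
    marker_side_px: int = 40
    marker_side_cm: float = 1.0
    background_rgb: tuple[int, int, int] = SKIN_RGB
    wound_rgb: tuple[int, int, int] = WOUND_RGB
    marker_rgb: tuple[int, int, int] = MARKER_RGB
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 64 or w < 64:
            raise ValueError("canvas must be at least 64x64")
        if min(self.wound_semi_axes) <= 0 or self.marker_side_px <= 0:
            raise ValueError("wound semi-axes and marker side must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")

    @property
    def analytic_wound_area_px(self) -> float:
        a, b = self.wound_semi_axes
        return math.pi * a * b

    @property
    def marker_area_px(self) -> int:
        return self.marker_side_px**2

    @property
    def cm2_per_pixel(self) -> float:
        return self.marker_side_cm**2 / self.marker_area_px

    @property
    def analytic_wound_area_cm2(self) -> float:
        return self.analytic_wound_area_px * self.cm2_per_pixel

    @property
    def wound_seed(self) -> tuple[int, int]:
        return (int(round(self.wound_center[0])), int(round(self.wound_center[1])))

    @property
    def marker_seed(self) -> tuple[int, int]:
        r, c = self.marker_origin
        return (r + self.marker_side_px // 2, c + self.marker_side_px // 2)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated image."""

    wound_mask: np.ndarray
    marker_mask: np.ndarray
    wound_area_px: int
    analytic_wound_area_px: float
    marker_area_px: int
    cm2_per_pixel: float
    wound_area_cm2: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wound_area_cm2", self.wound_area_px * self.cm2_per_pixel
        )


def _masks(spec: SyntheticWoundSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.shape
    wound = np.zeros((h, w), dtype=bool)
    rr, cc = _draw_ellipse(
        *spec.wound_center, *spec.wound_semi_axes, shape=(h, w)
    )
    wound[rr, cc] = True
    marker = np.zeros((h, w), dtype=bool)
    r0, c0 = spec.marker_origin
    r1, c1 = r0 + spec.marker_side_px, c0 + spec.marker_side_px
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError("marker square falls outside the canvas")
    marker[r0:r1, c0:c1] = True
    return wound, marker


def generate_wound_image(
    spec: SyntheticWoundSpec, capture_date: _dt.date | None = None
) -> tuple[WoundImage, SyntheticTruth]:
    """Render one synthetic photograph and its ground truth.

    Raises if the wound ellipse and the marker square overlap.
    """
    wound_mask, marker_mask = _masks(spec)
    if (wound_mask & marker_mask).any():
        raise ValueError("wound ellipse and reference marker overlap")
    h, w = spec.shape
    canvas = np.empty((h, w, 3))
    canvas[:] = np.asarray(spec.background_rgb) / 255.0
    canvas[wound_mask] = np.asarray(spec.wound_rgb) / 255.0
    canvas[marker_mask] = np.asarray(spec.marker_rgb) / 255.0
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    pixels = (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    image = WoundImage(
        pixels=pixels, capture_date=capture_date or _dt.date(2019, 6, 25)
    )
    truth = SyntheticTruth(
        wound_mask=wound_mask,
        marker_mask=marker_mask,
        wound_area_px=int(wound_mask.sum()),
        analytic_wound_area_px=spec.analytic_wound_area_px,
        marker_area_px=spec.marker_area_px,
        cm2_per_pixel=spec.cm2_per_pixel,
    )
    return image, truth


def generate_case_pair(
    spec_before: SyntheticWoundSpec,
    spec_after: SyntheticWoundSpec,
    date_before: _dt.date,
    date_after: _dt.date,
) -> tuple[tuple[WoundImage, SyntheticTruth], tuple[WoundImage, SyntheticTruth], AreaChange]:
    """Two dated images plus the expected area change from the ground truth.

    The expected rate uses the rasterized mask areas converted through each
    image's own marker scale, i.e. exactly what a perfect segmentation of
    the pair would measure.
    """
    if date_after <= date_before:
        raise ValueError(
            f"after date {date_after} must be strictly later than {date_before}"
        )
    before = generate_wound_image(spec_before, date_before)
    after = generate_wound_image(spec_after, date_after)
    expected = AreaChange(
        area_ref_cm2=before[1].wound_area_cm2,
        area_now_cm2=after[1].wound_area_cm2,
        days_elapsed=float((date_after - date_before).days),
    )
    return before, after, expected
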