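"""Sliding-window tiling of slide images.

Training patches come from an overlapping fixed-stride grid (default 400-px
window, 50-px stride) at each configured scale; tiles dominated by white
background are discarded. Test patches are concentric sets: three aligned
patches of sizes s, 2s, 4s sharing one center pixel, feeding the three
scale-specific classifiers.

Coordinates are 0-based (row, col) with half-open extents
[top, top+size) x [left, left+size). No padding anywhere: windows that do not
fit are simply not emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

__all__ = [
    "Patch",
    "ConcentricPatchSet",
    "TilingConfig",
    "grid_positions",
    "background_fraction",
    "filter_patches",
    "extract_training_patches",
    "extract_concentric_sets",
]


@dataclass(frozen=True, eq=False)
class Patch:
    """One image window: slide id, side length, top-left corner and pixels."""

    slide_id: str
    scale: int
    top_left: tuple[int, int]
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.pixels.shape[:2] != (self.scale, self.scale):
            raise ValueError(
                f"pixels shape {self.pixels.shape[:2]} does not match scale {self.scale}"
            )

    @property
    def center(self) -> tuple[int, int]:
        # for even sizes: the pixel just below/right of the geometric center,
        # so the s/2s/4s offsets are integral and alignment is exact
        return (self.top_left[0] + self.scale // 2, self.top_left[1] + self.scale // 2)


@dataclass(frozen=True, eq=False)
class ConcentricPatchSet:
    """Three aligned patches of sizes s, 2s, 4s sharing one center pixel."""

    small: Patch
    medium: Patch
    large: Patch

    def __post_init__(self) -> None:
        s = self.small.scale
        if (self.medium.scale, self.large.scale) != (2 * s, 4 * s):
            raise ValueError("scales must be s, 2s, 4s")
        if not (self.small.center == self.medium.center == self.large.center):
            raise ValueError("patches must share one center pixel")

    @property
    def center(self) -> tuple[int, int]:
        return self.small.center

    @property
    def slide_id(self) -> str:
        return self.small.slide_id


@dataclass(frozen=True)
class TilingConfig:
    """Tiling parameters.

    ``bg_saturation_max`` / ``bg_value_min`` define the background rule: a
    pixel is background iff its HSV saturation is below the first and its
    value above the second (near-white, unsaturated). The discard threshold
    ``max_background_fraction`` is strict — a tile is discarded only when its
    background fraction exceeds it.
    """

    train_window: int = 400
    stride: int = 50
    max_background_fraction: float = 0.25
    test_small_size: int = 100
    test_stride: int | None = None  # defaults to test_small_size
    bg_saturation_max: float = 0.08
    bg_value_min: float = 0.85
    scales: tuple[int, ...] = (400, 200, 100)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.max_background_fraction <= 1.0:
            raise ValueError("max_background_fraction must be in [0, 1]")

    @property
    def effective_test_stride(self) -> int:
        return self.test_small_size if self.test_stride is None else self.test_stride


def grid_positions(
    image_height: int, image_width: int, window: int, stride: int
) -> list[tuple[int, int]]:
    """Top-left corners of a full-fit sliding-window grid, row-major.

    Offsets are {0, stride, 2*stride, ...} per axis; per-axis count is
    floor((dim - window)/stride) + 1 when the window fits, else 0.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if image_height < window or image_width < window:
        return []
    rows = range(0, image_height - window + 1, stride)
    cols = range(0, image_width - window + 1, stride)
    return [(r, c) for r in rows for c in cols]


def _background_mask(pixels: np.ndarray, config: TilingConfig) -> np.ndarray:
    hsv = rgb2hsv(pixels)
    return (hsv[..., 1] < config.bg_saturation_max) & (hsv[..., 2] > config.bg_value_min)


def background_fraction(patch: Patch, config: TilingConfig | None = None) -> float:
    """Fraction of the patch's pixels classified as (near-white) background."""
    config = config or TilingConfig()
    return float(_background_mask(patch.pixels, config).mean())


def filter_patches(
    patches: list[Patch],
    max_background_fraction: float = 0.25,
    config: TilingConfig | None = None,
) -> list[Patch]:
    """Keep patches whose background fraction is <= the threshold (order kept)."""
    config = config or TilingConfig()
    return [p for p in patches if background_fraction(p, config) <= max_background_fraction]


def extract_training_patches(
    image: np.ndarray,
    slide_id: str,
    config: TilingConfig | None = None,
    scales: tuple[int, ...] | None = None,
) -> list[Patch]:
    """Overlapping training patches at each scale, background-filtered.

    Each scale gets its own full sliding-window grid with the configured
    stride; patches inherit their slide's class label downstream (weak,
    bag-level supervision).
    """
    config = config or TilingConfig()
    scales = scales if scales is not None else config.scales
    h, w = image.shape[:2]
    if h < min(scales) or w < min(scales):
        logger.warning("slide %s (%dx%d) smaller than every scale; no patches", slide_id, h, w)
    # precompute the background mask once; patch fractions are window means
    mask = _background_mask(image, config).astype(np.float64)
    integral = np.pad(mask.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    out: list[Patch] = []
    for scale in scales:
        for r, c in grid_positions(h, w, scale, config.stride):
            bg = (
                integral[r + scale, c + scale]
                - integral[r, c + scale]
                - integral[r + scale, c]
                + integral[r, c]
            ) / (scale * scale)
            if bg <= config.max_background_fraction:
                out.append(Patch(slide_id, scale, (r, c), image[r : r + scale, c : c + scale]))
    return out


def extract_concentric_sets(
    image: np.ndarray,
    slide_id: str,
    config: TilingConfig | None = None,
) -> list[ConcentricPatchSet]:
    """Concentric s/2s/4s test patch sets on the small-patch grid.

    Small patches are placed on a grid with the test stride; a set is emitted
    only if all three scales fit fully inside the image (boundary sets are
    dropped, never padded). Sets whose small patch fails the background
    filter are dropped.
    """
    config = config or TilingConfig()
    s = config.test_small_size
    h, w = image.shape[:2]
    out: list[ConcentricPatchSet] = []
    for r, c in grid_positions(h, w, s, config.effective_test_stride):
        rl, cl = r - 3 * s // 2, c - 3 * s // 2
        if rl < 0 or cl < 0 or rl + 4 * s > h or cl + 4 * s > w:
            continue
        small = Patch(slide_id, s, (r, c), image[r : r + s, c : c + s])
        if background_fraction(small, config) > config.max_background_fraction:
            continue
        rm, cm = r - s // 2, c - s // 2
        medium = Patch(slide_id, 2 * s, (rm, cm), image[rm : rm + 2 * s, cm : cm + 2 * s])
        large = Patch(slide_id, 4 * s, (rl, cl), image[rl : rl + 4 * s, cl : cl + 4 * s])
        out.append(ConcentricPatchSet(small=small, medium=medium, large=large))
    return out
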