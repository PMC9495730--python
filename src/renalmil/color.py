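"""Stain normalization by histogram specification in the lαβ opponent color space.

H&E staining varies between labs and scanners; downstream texture classifiers
are sensitive to that variation. The normalization here maps each image's
per-channel histograms in the decorrelated lαβ space (l achromatic,
α yellow–blue, β red–green) onto a reference image's histograms, then converts
back to RGB. A mean/variance-only ("reinhard") transfer is available as an
alternative through the same interface.

The RGB→LMS and LMS→lαβ matrices follow Reinhard et al.'s color-transfer
pathway and are pinned as module constants; the inverse matrices are computed
from them with ``numpy.linalg.inv`` so the round trip is exact to float
precision rather than limited by published rounded inverses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceProfile",
    "rgb_to_lab",
    "lab_to_rgb",
    "fit_reference",
    "normalize_image",
]

# Reinhard et al. color-transfer constants (pinned; see tests for a
# hand-computed pixel). RGB and LMS here are linear values in [0, 1].
RGB_TO_LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
LMS_TO_LAB = np.array(
    [
        [1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)],
        [1.0 / np.sqrt(6.0), 1.0 / np.sqrt(6.0), -2.0 / np.sqrt(6.0)],
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
    ]
)
LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)
LAB_TO_LMS = np.linalg.inv(LMS_TO_LAB)

#: floor applied to linear LMS before log10 so black pixels stay finite
LMS_EPS = 1e-6


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image (HxWx3, values 0–255) to lαβ.

    The pathway is RGB → linear LMS (fixed 3x3 matrix) → elementwise log10
    with an epsilon floor → lαβ (fixed matrix). Achromatic pixels map to
    α = β = 0.
    """
    image = _check_rgb(image)
    rgb = image.astype(np.float64) / 255.0
    lms = rgb @ RGB_TO_LMS.T
    lms = np.log10(np.maximum(lms, LMS_EPS))
    return lms @ LMS_TO_LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Convert an lαβ image back to 8-bit RGB, clamping to [0, 255]."""
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 lab image, got shape {lab.shape}")
    if not np.all(np.isfinite(lab)):
        raise ValueError("lab image contains non-finite values")
    lms = np.power(10.0, lab @ LAB_TO_LMS.T)
    rgb = lms @ LMS_TO_RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-channel quantile functions of a reference image in lαβ space.

    ``probs`` is a shared grid of cumulative probabilities in [0, 1];
    ``quantiles`` has shape (3, len(probs)) with one non-decreasing row per
    lαβ channel. ``bins`` records the grid resolution the profile was fitted
    with.
    """

    probs: np.ndarray
    quantiles: np.ndarray
    bins: int

    def __post_init__(self) -> None:
        if self.quantiles.shape != (3, self.probs.size):
            raise ValueError("quantiles must be 3 x len(probs)")
        if np.any(np.diff(self.quantiles, axis=1) < 0):
            raise ValueError("quantile functions must be non-decreasing")


def fit_reference(target: np.ndarray, bins: int = 1024) -> ReferenceProfile:
    """Estimate the lαβ quantile functions of a reference (target) image.

    All pixels participate — no tissue masking; background handling belongs
    to the tiling stage.
    """
    target = _check_rgb(target)
    if target.shape[0] * target.shape[1] == 0:
        raise ValueError("reference image is empty")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lab = rgb_to_lab(target).reshape(-1, 3)
    probs = np.linspace(0.0, 1.0, bins + 1)
    quantiles = np.quantile(lab, probs, axis=0).T  # (3, bins+1)
    return ReferenceProfile(probs=probs, quantiles=quantiles, bins=bins)


def _specification_channel(src: np.ndarray, probs: np.ndarray, quants: np.ndarray) -> np.ndarray:
    # empirical CDF of the source channel (average rank handles ties), then
    # the reference quantile at that probability, linearly interpolated
    order = np.sort(src)
    n = src.size
    lo = np.searchsorted(order, src, side="left")
    hi = np.searchsorted(order, src, side="right")
    cdf = (lo + hi) / (2.0 * n)
    return np.interp(cdf, probs, quants)


def normalize_image(
    source: np.ndarray,
    profile: ReferenceProfile,
    method: str = "specification",
) -> np.ndarray:
    """Map a source image's lαβ histograms onto the reference profile.

    ``method='specification'`` performs full per-channel histogram
    specification (quantile mapping, monotone within each channel);
    ``method='reinhard'`` only matches per-channel mean and standard
    deviation. Returns an 8-bit RGB image of the source's size.
    """
    source = _check_rgb(source)
    lab = rgb_to_lab(source)
    shape = lab.shape
    flat = lab.reshape(-1, 3)
    out = np.empty_like(flat)
    if method == "specification":
        for c in range(3):
            out[:, c] = _specification_channel(flat[:, c], profile.probs, profile.quantiles[c])
    elif method == "reinhard":
        # moments of the reference distribution recovered from its quantiles
        # via the inverse-CDF integral (trapezoid on the probability grid)
        for c in range(3):
            q = profile.quantiles[c]
            mu_t = np.trapezoid(q, profile.probs)
            var_t = np.trapezoid((q - mu_t) ** 2, profile.probs)
            mu_s = flat[:, c].mean()
            sd_s = flat[:, c].std()
            scale = np.sqrt(var_t) / sd_s if sd_s > 0 else 0.0
            out[:, c] = (flat[:, c] - mu_s) * scale + mu_t
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return lab_to_rgb(out.reshape(shape))
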