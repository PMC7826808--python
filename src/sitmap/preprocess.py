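"""Pressure-image noise reduction and normalization.

Two paths: (a) a binary mask from thresholding at 0.45 x the image mean,
cleaned by morphological opening then closing; (b) 3x3 Gaussian smoothing of
the raw image.  The smoothed image is multiplied by the mask and
L1-normalized so the result sums to 1, removing inter-subject weight
differences.  Every step is relative (threshold to the mean, normalization
to the sum), so the whole pipeline is exactly invariant to positive scaling
of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io import PressureImage

__all__ = ["PreprocessConfig", "binary_mask", "refine_mask", "gaussian_smooth", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    threshold_factor: float = 0.45   # threshold = factor * mean pressure
    gaussian_size: int = 3           # odd kernel side length
    gaussian_sigma: float = 0.8      # kernel width; renormalized to sum 1
    morph_radius: int = 1            # structuring-element radius (square)

    def __post_init__(self) -> None:
        if not self.threshold_factor > 0:
            raise ValueError("threshold_factor must be positive")
        if self.gaussian_size < 1 or self.gaussian_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be nonnegative")


def binary_mask(img: PressureImage, threshold_factor: float = 0.45) -> np.ndarray:
    """Mask of pixels strictly above ``threshold_factor`` x mean(img).

    The mean is over all pixels, zeros included.  An all-zero image yields an
    all-zero mask.
    """
    v = img.values
    thr = threshold_factor * v.mean()
    return (v > thr).astype(np.uint8)


def refine_mask(mask: np.ndarray, morph_radius: int = 1) -> np.ndarray:
    """Morphological opening then closing with a square element.

    Opening removes isolated specks (interference spikes); closing fills
    small holes inside the body region.
    """
    if morph_radius == 0:
        return np.asarray(mask, dtype=np.uint8)
    footprint = np.ones((2 * morph_radius + 1, 2 * morph_radius + 1), dtype=bool)
    m = np.asarray(mask, dtype=bool)
    m = morphology.closing(morphology.opening(m, footprint), footprint)
    return m.astype(np.uint8)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size, dtype=float) - (size - 1) / 2
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    return g / g.sum()


def gaussian_smooth(img: PressureImage, size: int = 3, sigma: float = 0.8) -> PressureImage:
    """Linear filtering with a normalized Gaussian kernel, reflect padding."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    kernel = _gaussian_kernel(size, sigma)
    out = ndimage.correlate(img.values, kernel, mode="reflect")
    return PressureImage(np.clip(out, 0.0, None), img.pixel_pitch_mm)


def preprocess(img: PressureImage, cfg: PreprocessConfig | None = None) -> PressureImage:
    """Full pipeline: mask ⊙ smoothed image, then L1 normalization (sum = 1)."""
    cfg = cfg or PreprocessConfig()
    mask = refine_mask(binary_mask(img, cfg.threshold_factor), cfg.morph_radius)
    smooth = gaussian_smooth(img, cfg.gaussian_size, cfg.gaussian_sigma)
    masked = smooth.values * mask
    total = masked.sum()
    if total <= 0:
        raise ValueError("empty image after masking")
    return PressureImage(masked / total, img.pixel_pitch_mm)
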