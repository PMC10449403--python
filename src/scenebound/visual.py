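"""Per-image visual-information metrics.

Three complementary measures of how much "stuff" an image contains:

* **edge density** — number of edge pixels from a Canny detector after a
  5x5 Gaussian blur (hysteresis thresholds 30/150 on the 0-255 intensity
  scale).  More contours, more complexity.
* **color entropy** — Shannon entropy of the joint A*/B* chromaticity
  histogram (CIELAB, 20x20 bins over a fixed [-110, 110] range per axis).
* **gist entropy** — Shannon entropy of a normalized multi-scale oriented
  filter-bank energy descriptor (3 scales with 8/6/4 orientations pooled
  over an 8x8 spatial grid: 1152 features).

Notes on dialects: grayscale conversion uses ITU-R 601 luma weights; the
blur sigma is derived from the kernel size by the common
``sigma = 0.3*((k-1)/2 - 1) + 0.8`` rule; CIELAB assumes sRGB primaries and
a D65 white point.  A*/B* values outside the fixed histogram range are
clipped into the end bins so that bins are image-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import feature as _skfeature
from skimage import transform as _sktransform

from .entropy import counts_to_probabilities, shannon_entropy

#: Fixed per-axis range of the A*/B* chromaticity histogram.
AB_RANGE: tuple[float, float] = (-110.0, 110.0)

#: Default gist configuration: 3 scales, 8/6/4 orientations, 8x8 grid.
GIST_ORIENTATIONS: tuple[int, ...] = (8, 6, 4)
GIST_GRID: int = 8
GIST_IMAGE_SIZE: int = 256

_LUMA_601 = np.array([0.299, 0.587, 0.114])


class DegenerateImageError(ValueError):
    """Raised when an image carries no usable signal for a metric."""


@dataclass(frozen=True)
class SceneImage:
    """An RGB raster with an identifier; the unit of visual-feature extraction."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"{self.image_id}: expected an (H, W, 3) RGB array")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"{self.image_id}: image smaller than 32x32")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError(f"{self.image_id}: channel values outside [0, 255]")
            object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class VisualFeatures:
    """The three visual-information numbers for one image."""

    image_id: str
    edge_density: int
    color_entropy: float
    gist_entropy: float


def to_grayscale(img: SceneImage) -> np.ndarray:
    """ITU-R 601 luma, as float on the 0-255 scale."""
    return img.pixels.astype(float) @ _LUMA_601


def _kernel_to_sigma(kernel: int) -> float:
    # Common kernel-size-to-sigma rule for a k x k Gaussian blur.
    return 0.3 * ((kernel - 1) * 0.5 - 1.0) + 0.8


def compute_edge_density(
    img: SceneImage,
    blur_kernel: int = 5,
    low_threshold: float = 30.0,
    high_threshold: float = 150.0,
) -> int:
    """Count Canny edge pixels after Gaussian smoothing.

    ``low_threshold``/``high_threshold`` are hysteresis bounds on gradient
    magnitude, interpreted on the 0-255 intensity scale.
    """
    if not 0 <= low_threshold <= high_threshold:
        raise ValueError("require 0 <= low_threshold <= high_threshold")
    if blur_kernel < 1 or blur_kernel > min(img.height, img.width):
        raise ValueError("blur kernel must be >= 1 and fit inside the image")
    gray = to_grayscale(img)
    edges = _skfeature.canny(
        gray,
        sigma=_kernel_to_sigma(blur_kernel),
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )
    return int(edges.sum())


def color_histogram(img: SceneImage, bins_per_axis: int = 20) -> np.ndarray:
    """Joint A*/B* count histogram with image-independent bin edges."""
    if bins_per_axis < 2:
        raise ValueError("bins_per_axis must be >= 2")
    lab = _skcolor.rgb2lab(img.pixels.astype(float) / 255.0)
    lo, hi = AB_RANGE
    a = np.clip(lab[..., 1].ravel(), lo, np.nextafter(hi, lo))
    b = np.clip(lab[..., 2].ravel(), lo, np.nextafter(hi, lo))
    edges = np.linspace(lo, hi, bins_per_axis + 1)
    hist, _, _ = np.histogram2d(a, b, bins=(edges, edges))
    return hist


def compute_color_entropy(img: SceneImage, bins_per_axis: int = 20) -> float:
    """Entropy (bits) of the A*/B* chromaticity histogram; 0 for flat color."""
    hist = color_histogram(img, bins_per_axis=bins_per_axis)
    return shannon_entropy(counts_to_probabilities(hist))


@lru_cache(maxsize=8)
def gist_filter_bank(
    size: int = GIST_IMAGE_SIZE,
    orientations_per_scale: tuple[int, ...] = GIST_ORIENTATIONS,
) -> np.ndarray:
    """Frequency-domain oriented Gabor-type transfer functions.

    Returns an array of shape ``(n_filters, size, size)``.  Filters are
    Gaussian-tuned in radial frequency (centres 0.25, 0.125, 0.0625
    cycles/pixel across scales) and in orientation modulo pi, so each is a
    symmetric two-lobed real transfer function.
    """
    freqs = np.fft.fftfreq(size)
    fx, fy = np.meshgrid(freqs, freqs)  # fy varies along rows
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)

    filters = []
    for scale, n_orient in enumerate(orientations_per_scale):
        f0 = 0.25 / (2.0**scale)
        sigma_r = 0.45 * f0
        sigma_t = 0.6 * np.pi / n_orient
        radial = np.exp(-((r - f0) ** 2) / (2.0 * sigma_r**2))
        radial[r == 0] = 0.0  # kill DC
        for k in range(n_orient):
            t0 = k * np.pi / n_orient
            dt = np.mod(theta - t0 + np.pi / 2.0, np.pi) - np.pi / 2.0
            filters.append(radial * np.exp(-(dt**2) / (2.0 * sigma_t**2)))
    return np.stack(filters)


def compute_gist(
    img: SceneImage,
    orientations_per_scale: Sequence[int] = GIST_ORIENTATIONS,
    grid: int = GIST_GRID,
) -> np.ndarray:
    """Normalized gist descriptor: filter energies pooled on a ``grid x grid`` mesh.

    The grayscale image is resized to a power-of-two square
    (:data:`GIST_IMAGE_SIZE`) for FFT convenience, mean-removed, filtered by
    the oriented bank, and each filter's magnitude response is averaged
    within each grid cell.  The concatenated vector (length
    ``sum(orientations) * grid**2``; 1152 by default) is normalized to sum
    to 1 so it can be read as a probability distribution.

    Raises
    ------
    DegenerateImageError
        If total filter energy is ~0 (e.g., a constant image), since a
        sum-to-1 normalization would be meaningless.
    """
    size = GIST_IMAGE_SIZE
    if size % grid != 0:
        raise ValueError("grid must divide the internal image size")
    gray = to_grayscale(img)
    if gray.shape != (size, size):
        gray = _sktransform.resize(
            gray, (size, size), anti_aliasing=True, mode="reflect"
        )
    gray = gray - gray.mean()
    spectrum = np.fft.fft2(gray)
    bank = gist_filter_bank(size, tuple(orientations_per_scale))

    cell = size // grid
    pooled = []
    for transfer in bank:
        energy = np.abs(np.fft.ifft2(spectrum * transfer))
        blocks = energy.reshape(grid, cell, grid, cell).mean(axis=(1, 3))
        pooled.append(blocks.ravel())
    vec = np.concatenate(pooled)
    total = vec.sum()
    if total < 1e-10:
        raise DegenerateImageError(
            f"{img.image_id}: zero filter energy (constant image?)"
        )
    return vec / total


def compute_gist_entropy(g: np.ndarray) -> float:
    """Entropy (bits) of a normalized gist descriptor."""
    return shannon_entropy(g)


def extract_visual_features(
    img: SceneImage,
    blur_kernel: int = 5,
    low_threshold: float = 30.0,
    high_threshold: float = 150.0,
    bins_per_axis: int = 20,
) -> VisualFeatures:
    """All three visual metrics for one image."""
    return VisualFeatures(
        image_id=img.image_id,
        edge_density=compute_edge_density(
            img, blur_kernel=blur_kernel,
            low_threshold=low_threshold, high_threshold=high_threshold,
        ),
        color_entropy=compute_color_entropy(img, bins_per_axis=bins_per_axis),
        gist_entropy=compute_gist_entropy(compute_gist(img)),
    )


def visual_feature_table(images: Sequence[SceneImage], **params) -> pd.DataFrame:
    """Visual features for a collection of images, one row per image."""
    rows = [extract_visual_features(img, **params) for img in images]
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in rows],
            "edge_density": [r.edge_density for r in rows],
            "color_entropy": [r.color_entropy for r in rows],
            "gist_entropy": [r.gist_entropy for r in rows],
        }
    )
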