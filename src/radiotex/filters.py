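"""Derived images consumed by the feature families.

Three filters are provided:

* Sobel gradient magnitude (3x3 kernels, reflect padding), with the mask eroded
  by one pixel so no stencil reads across the tumor boundary.
* One level of the 2D orthonormal Haar wavelet transform.  For each 2x2 block
  ``(a b / c d)`` the four sub-band coefficients are

      approximate = (a+b+c+d)/2      horizontal = (a+b-c-d)/2
      vertical    = (a-b+c-d)/2      diagonal   = (a-b-c+d)/2

  which conserves energy exactly (sum of squared coefficients equals sum of
  squared padded input pixels) and inverts perfectly.  Odd dimensions are
  symmetric-padded to even before the transform.  Band masks are the 2x2
  logical-OR downsample of the (padded) tumor mask, keeping boundary texture.
* A single global 9-bin histogram of oriented gradients over the masked,
  eroded ROI: unsigned orientation in [0, 180) degrees, magnitude-weighted
  votes split linearly between the two nearest bin centers (10, 30, ..., 170
  degrees, wrapping 170 <-> 10 across the fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .io_preprocess import MIN_MASK_PIXELS, RoiImage

HOG_N_BINS = 9
_BIN_WIDTH = 180.0 / HOG_N_BINS
HOG_BIN_CENTERS = _BIN_WIDTH / 2 + _BIN_WIDTH * np.arange(HOG_N_BINS)


@dataclass
class WaveletBands:
    """The four single-level Haar sub-band images and their downsampled masks."""

    approximate: np.ndarray
    horizontal: np.ndarray
    vertical: np.ndarray
    diagonal: np.ndarray
    mask: np.ndarray  # 2x2 logical-OR downsample of the padded input mask

    def items(self):
        return (
            ("wav_a", self.approximate),
            ("wav_h", self.horizontal),
            ("wav_v", self.vertical),
            ("wav_d", self.diagonal),
        )


@dataclass
class OrientationHistogram:
    """9 normalized orientation-bin masses over [0, 180) degrees."""

    bin_values: np.ndarray
    bin_centers: np.ndarray


def _sobel_xy(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = ndimage.sobel(pixels, axis=1, mode="reflect")
    gy = ndimage.sobel(pixels, axis=0, mode="reflect")
    return gx, gy


def eroded_mask(mask: np.ndarray) -> np.ndarray:
    """Shrink the mask by one pixel (8-connected) so 3x3 stencils stay inside."""
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def gradient_image(roi: RoiImage) -> RoiImage:
    """Per-pixel Sobel gradient magnitude with a 1-pixel-eroded mask."""
    inner = eroded_mask(roi.mask)
    if int(inner.sum()) < MIN_MASK_PIXELS:
        raise DegenerateInputError(
            f"mask shrinks to {int(inner.sum())} < {MIN_MASK_PIXELS} pixels after erosion"
        )
    gx, gy = _sobel_xy(roi.pixels)
    mag = np.hypot(gx, gy)
    return replace(roi, pixels=mag, mask=inner)


def _pad_even(arr: np.ndarray) -> np.ndarray:
    pr, pc = arr.shape[0] % 2, arr.shape[1] % 2
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="symmetric")
    return arr


def haar_dwt(roi: RoiImage) -> WaveletBands:
    """Single-level orthonormal 2D Haar transform of the ROI image."""
    px = _pad_even(roi.pixels)
    mk = _pad_even(roi.mask)
    a = px[0::2, 0::2]
    b = px[0::2, 1::2]
    c = px[1::2, 0::2]
    d = px[1::2, 1::2]
    band_mask = mk[0::2, 0::2] | mk[0::2, 1::2] | mk[1::2, 0::2] | mk[1::2, 1::2]
    return WaveletBands(
        approximate=(a + b + c + d) / 2.0,
        horizontal=(a + b - c - d) / 2.0,
        vertical=(a - b + c - d) / 2.0,
        diagonal=(a - b - c + d) / 2.0,
        mask=band_mask,
    )


def haar_idwt(bands: WaveletBands) -> np.ndarray:
    """Inverse of :func:`haar_dwt`; returns the (padded) image."""
    ap, h, v, d = bands.approximate, bands.horizontal, bands.vertical, bands.diagonal
    out = np.empty((2 * ap.shape[0], 2 * ap.shape[1]), dtype=np.float64)
    out[0::2, 0::2] = (ap + h + v + d) / 2.0
    out[0::2, 1::2] = (ap + h - v - d) / 2.0
    out[1::2, 0::2] = (ap - h + v - d) / 2.0
    out[1::2, 1::2] = (ap - h - v + d) / 2.0
    return out


def hog_histogram(roi: RoiImage) -> OrientationHistogram:
    """Global magnitude-weighted orientation histogram of the masked ROI.

    All-zero gradients (a flat ROI) yield the declared degenerate result: a
    uniform histogram, with a warning.
    """
    inner = eroded_mask(roi.mask)
    if int(inner.sum()) < MIN_MASK_PIXELS:
        raise DegenerateInputError("mask too small after erosion for HoG")
    gx, gy = _sobel_xy(roi.pixels)
    mag = np.hypot(gx, gy)[inner]
    total = float(mag.sum())
    if total == 0.0:
        warnings.warn("all-zero gradients in ROI; HoG histogram set to uniform")
        return OrientationHistogram(
            bin_values=np.full(HOG_N_BINS, 1.0 / HOG_N_BINS), bin_centers=HOG_BIN_CENTERS.copy()
        )
    theta = np.degrees(np.arctan2(gy, gx))[inner] % 180.0  # unsigned orientation
    # linear vote split between the two nearest bin centers, wrapping at 180
    pos = theta / _BIN_WIDTH - 0.5
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    hist = np.zeros(HOG_N_BINS, dtype=np.float64)
    np.add.at(hist, lo % HOG_N_BINS, mag * (1.0 - frac))
    np.add.at(hist, (lo + 1) % HOG_N_BINS, mag * frac)
    return OrientationHistogram(bin_values=hist / total, bin_centers=HOG_BIN_CENTERS.copy())
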