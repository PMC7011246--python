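"""Reading ROI image/mask pairs, intensity normalization, and gray-level quantization.

All downstream texture features operate on a single 2D slice with a binary tumor
mask.  Intensities are min-max normalized inside the mask so that features built
on quantized gray levels are invariant to affine intensity rescaling of the raw
acquisition (scanner gain/offset).  Gray-level quantization is equal-width
binning of [0, 1]; the level index is 1-based inside the mask and 0 outside so
that 0 can never be confused with a valid gray level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyMaskError,
    ShapeMismatchError,
)

#: minimum number of foreground pixels required for texture matrices
MIN_MASK_PIXELS = 16


@dataclass
class RoiImage:
    """A 2D intensity array with a binary tumor mask.

    Shapes are reported as (height, width); indices are 0-based (row, col).
    """

    pixels: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.mask = np.asarray(self.mask) != 0
        if self.pixels.ndim != 2:
            raise ShapeMismatchError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.pixels.shape != self.mask.shape:
            raise ShapeMismatchError(
                f"image shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise DegenerateInputError("non-finite intensities in ROI image")
        if not self.mask.any():
            raise EmptyMaskError(f"empty mask for subject '{self.subject_id}'")
        if int(self.mask.sum()) < MIN_MASK_PIXELS:
            raise DegenerateInputError(
                f"mask has {int(self.mask.sum())} < {MIN_MASK_PIXELS} foreground pixels"
            )

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass
class QuantizedImage:
    """Gray levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask) != 0
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ConfigurationError("quantized levels outside [1, n_levels] inside mask")


def _load_2d(path: Path) -> np.ndarray:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ShapeMismatchError(f"{path}: expected a single 2D slice, got shape {arr.shape}")
        # NIfTI stores (x, y); transpose to (row, col) so a PNG written from the
        # same array round-trips to identical pixel values at identical indices.
        return arr.T
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # RGB(A) export of a grayscale map
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ShapeMismatchError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return arr


def read_roi(image_path: str | Path, mask_path: str | Path, subject_id: str = "") -> RoiImage:
    """Read an image/mask pair (PNG/TIFF or single-slice NIfTI).

    The mask is binarized at > 0.  Raises :class:`ShapeMismatchError` when the
    two arrays disagree in shape and :class:`EmptyMaskError` when the mask has
    no foreground.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise IOError(f"file not found: {p}")
    pixels = _load_2d(image_path)
    mask = _load_2d(mask_path)
    if pixels.shape != mask.shape:
        raise ShapeMismatchError(
            f"image shape {pixels.shape} != mask shape {mask.shape} "
            f"({image_path.name} / {mask_path.name})"
        )
    if not (mask > 0).any():
        raise EmptyMaskError(f"empty mask in {mask_path}")
    return RoiImage(pixels=pixels, mask=mask > 0, subject_id=subject_id or image_path.stem)


def normalize_masked(values: np.ndarray, mask: np.ndarray, what: str = "ROI") -> np.ndarray:
    """Min-max map masked values to [0, 1]; zeros outside the mask.

    A constant masked region maps to all zeros with a warning (the texture of a
    perfectly flat region is legitimately empty, not an error).
    """
    out = np.zeros_like(values, dtype=np.float64)
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi == lo:
        warnings.warn(f"constant {what}: all masked intensities equal {lo}; normalized to 0")
        return out
    out[mask] = (inside - lo) / (hi - lo)
    return out


def normalize_roi(roi: RoiImage) -> RoiImage:
    """Per-subject min-max normalization of masked intensities to [0, 1]."""
    return replace(roi, pixels=normalize_masked(roi.pixels, roi.mask))


def quantize(roi: RoiImage, n_levels: int = 32) -> QuantizedImage:
    """Equal-width quantization of normalized intensities into 1..n_levels.

    Bin edges split [0, 1] evenly; the value 1.0 is assigned to the top level.
    """
    if n_levels < 2:
        raise ConfigurationError(f"n_levels must be >= 2, got {n_levels}")
    vals = roi.pixels
    if vals[roi.mask].min() < 0 or vals[roi.mask].max() > 1:
        raise ConfigurationError("quantize expects a normalized ROI (masked values in [0, 1])")
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[roi.mask] = np.minimum((vals[roi.mask] * n_levels).astype(np.int64), n_levels - 1) + 1
    return QuantizedImage(levels=levels, n_levels=n_levels, mask=roi.mask, source=roi.subject_id)
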