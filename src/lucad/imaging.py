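"""Reading, writing and normalization of CT slices and binary masks.

A slice is a single 2D gray-level image with isotropic physical pixel
spacing. All downstream stages assume intensities normalized to [0, 1];
normalization here is per-slice min–max (a constant slice maps to all
zeros by convention). Masks are plain boolean arrays congruent with the
slice raster, saved losslessly as 8-bit PNG (0/255).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom

#: Fallback physical pixel size when a file carries no spacing attribute:
#: 512 px spanning a ~358 mm chest field of view.
DEFAULT_PIXEL_SPACING_MM = 0.7

MIN_SIDE = 32


@dataclass
class CTSlice:
    """One gray-level CT slice with intensities in [0, 1].

    Attributes
    ----------
    pixels : ndarray of float64, shape (H, W)
        Normalized intensities in the unit interval.
    pixel_spacing_mm : float
        Physical edge length of one pixel (isotropic), millimetres.
    slice_id : str
        Opaque identifier, typically the source file stem.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    slice_id: str = field(default="")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(f"slice must be at least {MIN_SIDE}x{MIN_SIDE}, got {h}x{w}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"pixel values must lie in [0, 1]; found range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CTSlice":
        """Return a copy carrying new pixel data but the same metadata."""
        return CTSlice(pixels=pixels, pixel_spacing_mm=self.pixel_spacing_mm,
                       slice_id=self.slice_id)


def normalize_minmax(raw: np.ndarray) -> np.ndarray:
    """Min–max rescale an array to [0, 1]; a constant array maps to zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def read_dicom_slice(path: str | Path, default_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> CTSlice:
    """Read one single-frame grayscale DICOM file as a normalized CTSlice.

    The stored rescale slope/intercept (if any) are applied before min–max
    normalization; the physical spacing is taken from ``PixelSpacing`` and
    falls back to `default_spacing_mm` (with a warning) when absent.
    """
    path = Path(path)
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame 2D DICOM, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    raw = arr.astype(np.float64) * slope + intercept

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        spacing_mm = float(spacing[0])
    else:
        warnings.warn(
            f"{path}: no PixelSpacing attribute; using default {default_spacing_mm} mm",
            stacklevel=2,
        )
        spacing_mm = default_spacing_mm
    return CTSlice(pixels=normalize_minmax(raw), pixel_spacing_mm=spacing_mm,
                   slice_id=path.stem)


def read_image(path: str | Path, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> CTSlice:
    """Read an 8/16-bit grayscale raster (PNG etc.) as a normalized CTSlice."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: color image; convert to single-channel grayscale before reading"
        )
    return CTSlice(pixels=normalize_minmax(arr), pixel_spacing_mm=pixel_spacing_mm,
                   slice_id=path.stem)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a boolean mask."""
    arr = np.asarray(arr)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be strictly binary")
        arr = arr.astype(bool)
    return arr


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask losslessly as 8-bit PNG (False→0, True→255)."""
    mask = as_mask(mask)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`.

    If `shape` is given, the stored raster must match it exactly.
    """
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask file must be single-channel")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"{path}: mask shape {arr.shape} != expected {tuple(shape)}")
    return arr > 0
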