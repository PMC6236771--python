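"""Lung volume extraction (LUVEM), an Otsu baseline, and overlap metrics.

LUVEM selects candidate lung pixels by a dual intensity threshold
(0.25 < intensity < 0.65 on the enhanced slice), removes any candidate
component touching the image border (bright or ambiguous edge regions),
then applies erosion, dilation and hole filling, in that order. Hole
filling is what recovers nodules and vessels that the threshold excluded
from the lung interior.

Segmentation overlap is quantified with the Jaccard (union overlap) and
Dice (mean overlap) coefficients:

    J(S1, S2) = |S1 ∩ S2| / |S1 ∪ S2|
    D(S1, S2) = 2 |S1 ∩ S2| / (|S1| + |S2|) = 2J / (1 + J)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion
from skimage.segmentation import clear_border

from lucad.imaging import CTSlice, as_mask


@dataclass
class LuvemConfig:
    low_threshold: float = 0.25
    high_threshold: float = 0.65
    erode_radius: int = 2
    dilate_radius: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_threshold < self.high_threshold <= 1.0):
            raise ValueError("need 0 <= low < high <= 1")
        if self.erode_radius < 1 or self.dilate_radius < 1:
            raise ValueError("morphology radii must be >= 1")


def _border_clear_and_morph(candidate: np.ndarray, erode_radius: int,
                            dilate_radius: int) -> np.ndarray:
    """Shared LUVEM steps 2–3: drop border-connected components, then
    erode → dilate → fill holes."""
    # 4-connectivity for the border-touching components
    labels, _ = ndimage.label(candidate, structure=ndimage.generate_binary_structure(2, 1))
    kept = clear_border(labels) > 0
    if not kept.any():
        return kept
    out = erosion(kept, disk(erode_radius))
    out = dilation(out, disk(dilate_radius))
    out = ndimage.binary_fill_holes(out)
    return out


def luvem_extract(ct: CTSlice, config: LuvemConfig | None = None
                  ) -> tuple[np.ndarray, CTSlice]:
    """Extract the lung fields from an enhanced slice.

    Returns ``(lung_mask, lung_image)`` where `lung_image` carries the
    original gray levels inside the mask and zero elsewhere (the
    "converted back to gray-scale" step). An empty mask is returned with
    a warning, not an exception, so batch runs survive degenerate slices.
    """
    config = config or LuvemConfig()
    candidate = (ct.pixels > config.low_threshold) & (ct.pixels < config.high_threshold)
    mask = _border_clear_and_morph(candidate, config.erode_radius, config.dilate_radius)
    if not mask.any():
        warnings.warn("LUVEM produced an empty lung mask", stacklevel=2)
    lung_image = ct.with_pixels(np.where(mask, ct.pixels, 0.0))
    return mask, lung_image


def otsu_extract(ct: CTSlice, erode_radius: int = 2, dilate_radius: int = 4) -> np.ndarray:
    """Otsu-threshold baseline: lung = below-threshold side, then the same
    border-removal and morphology as LUVEM for comparability."""
    if np.unique(ct.pixels).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    t = threshold_otsu(ct.pixels)
    return _border_clear_and_morph(ct.pixels < t, erode_radius, dilate_radius)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_mask(a), as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a∩b|/|a∪b|; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b|/(|a|+|b|); 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return float(2 * np.logical_and(a, b).sum() / total)
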