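"""Image enhancement: median denoising, Laplacian sharpening, histogram equalization.

The enhancement chain runs median → sharpen → equalize: denoising
precedes differentiation so the Laplacian does not amplify grain, and
equalization runs last so that the fixed lung-extraction thresholds see
contrast-normalized intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_hist

from lucad.imaging import CTSlice

# 4-neighbour Laplacian; subtracting it sharpens for this sign convention.
_LAPLACIAN = np.array([[0.0, 1.0, 0.0],
                       [1.0, -4.0, 1.0],
                       [0.0, 1.0, 0.0]])


@dataclass
class EnhanceConfig:
    """Parameters of the enhancement chain.

    median_kernel : odd window size in pixels (>= 3).
    sharpen_weight : nonnegative Laplacian subtraction weight; 0 disables.
    equalize_bins : histogram bins for equalization (>= 2).
    """

    median_kernel: int = 3
    sharpen_weight: float = 0.5
    equalize_bins: int = 256

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if self.sharpen_weight < 0:
            raise ValueError("sharpen_weight must be >= 0")
        if self.equalize_bins < 2:
            raise ValueError("equalize_bins must be >= 2")


def median_denoise(ct: CTSlice, kernel: int = 3) -> CTSlice:
    """Median-filter the slice with a kernel×kernel window (reflect padding)."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 3")
    out = ndimage.median_filter(ct.pixels, size=kernel, mode="reflect")
    return ct.with_pixels(out)


def laplacian_sharpen(ct: CTSlice, weight: float = 0.5) -> CTSlice:
    """Sharpen by subtracting the weighted 4-neighbour Laplacian, clipped to [0, 1]."""
    if weight < 0:
        raise ValueError("sharpen weight must be >= 0")
    if weight == 0:
        return ct.with_pixels(ct.pixels.copy())
    lap = ndimage.convolve(ct.pixels, _LAPLACIAN, mode="reflect")
    return ct.with_pixels(np.clip(ct.pixels - weight * lap, 0.0, 1.0))


def hist_equalize(ct: CTSlice, bins: int = 256) -> CTSlice:
    """Histogram-equalize via the standard CDF mapping on a binned histogram.

    The mapping is monotone nondecreasing in input intensity, so ordering
    of gray levels is preserved.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return ct.with_pixels(equalize_hist(ct.pixels, nbins=bins))


def enhance(ct: CTSlice, config: EnhanceConfig | None = None) -> CTSlice:
    """Run the full enhancement chain: median → Laplacian sharpen → equalize."""
    config = config or EnhanceConfig()
    out = median_denoise(ct, config.median_kernel)
    out = laplacian_sharpen(out, config.sharpen_weight)
    return hist_equalize(out, config.equalize_bins)
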