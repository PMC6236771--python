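"""The 123-dimensional nodule feature vector.

Four families, concatenated in a fixed order:

* SSF (6): first-order statistics of the masked intensity sample —
  mean, standard deviation, variance, skewness, kurtosis, histogram
  entropy (bits, 256 bins). Population moments; zero-variance samples
  get skewness = kurtosis = 0 by convention so vectors stay finite.
* SBF (16): shape descriptors of the nodule mask — area, perimeter,
  circularity, eccentricity, solidity, extent, equivalent diameter,
  major/minor axis, aspect ratio, convex area/perimeter, convexity,
  compactness, radial-distance mean and standard deviation. Boundary
  irregularity (spiculation) raises radial-distance spread and lowers
  circularity.
* GTF (22 × 4 = 88): Haralick-family descriptors of the gray-level
  co-occurrence matrix at displacement d=2 along 0°, 45°, 90° and 135°,
  concatenated angle-major.
* TEF (13): relative energies of a 4-level 2D Daubechies-2 wavelet
  decomposition — 12 detail subbands (H, V, D at each level) plus the
  level-4 approximation; they are nonnegative and sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from skimage import measure
from skimage.feature import graycomatrix

from lucad.imaging import as_mask

# ---------------------------------------------------------------------------
# configuration and naming


@dataclass
class GLCMConfig:
    """Co-occurrence matrix settings: displacement `distance` pixels along
    each of `angles` (degrees); intensities quantized to `levels`
    equal-width bins on [0, 1]; symmetrized and normalized to sum 1."""

    distance: int = 2
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    levels: int = 16
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


SSF_NAMES = ("ssf_mean", "ssf_std", "ssf_variance", "ssf_skewness",
             "ssf_kurtosis", "ssf_entropy")

SBF_NAMES = ("sbf_area", "sbf_perimeter", "sbf_circularity", "sbf_eccentricity",
             "sbf_solidity", "sbf_extent", "sbf_equivalent_diameter",
             "sbf_major_axis", "sbf_minor_axis", "sbf_aspect_ratio",
             "sbf_convex_area", "sbf_convex_perimeter", "sbf_convexity",
             "sbf_compactness", "sbf_radial_mean", "sbf_radial_std")

GLCM_DESCRIPTORS = (
    "autocorrelation", "contrast", "correlation", "cluster_prominence",
    "cluster_shade", "dissimilarity", "asm", "entropy", "homogeneity",
    "max_probability", "sum_of_squares", "sum_average", "sum_entropy",
    "sum_variance", "difference_variance", "difference_entropy",
    "imc1", "imc2", "inverse_difference", "inverse_difference_norm",
    "inverse_moment_norm", "max_corr_coeff",
)

TEF_NAMES = tuple(
    f"tef_l{level}_{band}" for level in (1, 2, 3, 4) for band in ("h", "v", "d")
) + ("tef_approx",)


def _gtf_names(angles: tuple[float, ...]) -> tuple[str, ...]:
    return tuple(f"gtf_a{int(a)}_{d}" for a in angles for d in GLCM_DESCRIPTORS)


#: Stable names of the full 123-element vector (default GLCM angles).
FEATURE_NAMES: tuple[str, ...] = (
    SSF_NAMES + SBF_NAMES + _gtf_names(GLCMConfig().angles) + TEF_NAMES
)
assert len(FEATURE_NAMES) == 123


@dataclass
class FeatureVector:
    """Ordered named feature record for one nodule."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values length must match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# SSF — first-order statistics


def ssf_features(sample: np.ndarray) -> np.ndarray:
    """First-order statistics of an intensity sample (>= 2 pixels)."""
    sample = np.asarray(sample, dtype=np.float64).ravel()
    if sample.size < 2:
        raise ValueError("need at least 2 pixels for first-order statistics")
    mean = sample.mean()
    if np.ptp(sample) == 0:  # exactly constant: all moments degenerate
        dev = np.zeros_like(sample)
        var = std = 0.0
    else:
        dev = sample - mean
        var = float((dev**2).mean())  # population
        std = np.sqrt(var)
    if var == 0:
        skew = kurt = 0.0
    else:
        skew = float((dev**3).mean() / std**3)
        kurt = float((dev**4).mean() / var**2)  # Pearson (non-excess)
    hist, _ = np.histogram(sample, bins=256, range=(0.0, 1.0))
    p = hist[hist > 0] / sample.size
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([mean, std, var, skew, kurt, entropy])


# ---------------------------------------------------------------------------
# SBF — shape descriptors


def _boundary_radial_distances(mask: np.ndarray) -> np.ndarray:
    # border_value=0 so masks touching the ROI edge still have a boundary
    boundary = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3), bool),
                                              border_value=0)
    rr, cc = np.nonzero(boundary)
    crow, ccol = np.nonzero(mask)
    centroid = (crow.mean(), ccol.mean())
    return np.hypot(rr - centroid[0], cc - centroid[1])


def sbf_features(mask: np.ndarray) -> np.ndarray:
    """The 16 shape descriptors of a nonempty nodule mask (largest
    connected component is used if several are present)."""
    mask = as_mask(mask)
    if not mask.any():
        raise ValueError("empty mask has no shape features")
    labeled, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    props = measure.regionprops(mask.astype(np.uint8))[0]

    area = float(props.area)
    # Crofton estimator: nearly unbiased on rasterized smooth shapes
    perimeter = max(float(measure.perimeter_crofton(mask, directions=4)), 1.0)
    circularity = 4.0 * np.pi * area / perimeter**2
    convex = props.image_convex
    convex_area = float(props.area_convex)
    convex_perimeter = max(float(measure.perimeter_crofton(convex, directions=4)), 1.0)
    minor = float(props.axis_minor_length)
    major = float(props.axis_major_length)
    aspect = major / minor if minor > 0 else 1.0
    radial = _boundary_radial_distances(mask)
    return np.array([
        area,
        perimeter,
        circularity,
        float(props.eccentricity),
        float(props.solidity),
        float(props.extent),
        float(props.equivalent_diameter_area),
        major,
        minor,
        aspect,
        convex_area,
        convex_perimeter,
        convex_perimeter / perimeter,
        perimeter**2 / area,
        float(radial.mean()),
        float(radial.std()),
    ])


# ---------------------------------------------------------------------------
# GTF — GLCM texture


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 1] intensities into `levels` bins."""
    q = np.floor(np.asarray(pixels, dtype=np.float64) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(roi_pixels: np.ndarray, config: GLCMConfig, angle_deg: float) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one angle."""
    roi_pixels = np.asarray(roi_pixels, dtype=np.float64)
    if min(roi_pixels.shape) <= config.distance:
        raise ValueError("ROI smaller than the co-occurrence displacement")
    q = quantize(roi_pixels, config.levels)
    m = graycomatrix(q, distances=[config.distance],
                     angles=[np.deg2rad(angle_deg)], levels=config.levels,
                     symmetric=config.symmetric, normed=False)[:, :, 0, 0]
    total = m.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at this displacement")
    return (m / total if config.normalized else m).astype(np.float64)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_descriptors(p: np.ndarray) -> np.ndarray:
    """The 22 texture descriptors of one normalized GLCM.

    Indices are 0-based gray levels; marginals px/py, sum distribution
    p_{x+y} and difference distribution p_{|x-y|} follow the classic
    definitions. Degenerate cases (zero marginal variance) fall back to
    correlation = 1 and information measures = 0.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()

    autocorr = (ii * jj * p).sum()
    contrast = ((ii - jj) ** 2 * p).sum()
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    dev = ii + jj - mu_x - mu_y
    cluster_prom = (dev**4 * p).sum()
    cluster_shade = (dev**3 * p).sum()
    dissimilarity = (np.abs(ii - jj) * p).sum()
    asm = (p**2).sum()
    entropy = -_xlog2(p).sum()
    homogeneity = (p / (1.0 + (ii - jj) ** 2)).sum()
    max_prob = p.max()
    sum_squares = (((ii - mu_x) ** 2) * p).sum()

    # sum / difference distributions
    ksum = np.arange(2 * n - 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    kdiff = np.arange(n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    sum_avg = (ksum * p_sum).sum()
    sum_entropy = -_xlog2(p_sum).sum()
    sum_var = ((ksum - sum_avg) ** 2 * p_sum).sum()
    diff_avg = (kdiff * p_diff).sum()
    diff_var = ((kdiff - diff_avg) ** 2 * p_diff).sum()
    diff_entropy = -_xlog2(p_diff).sum()

    # information measures of correlation
    hx = -_xlog2(px).sum()
    hy = -_xlog2(py).sum()
    pxy = np.outer(px, py)
    valid = (p > 0) & (pxy > 0)
    hxy1 = -(p[valid] * np.log2(pxy[valid])).sum()
    hxy2 = -_xlog2(pxy).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inv_diff = (p / (1.0 + np.abs(ii - jj))).sum()
    inv_diff_norm = (p / (1.0 + np.abs(ii - jj) / n)).sum()
    inv_moment_norm = (p / (1.0 + (ii - jj) ** 2 / n**2)).sum()

    # maximal correlation coefficient: sqrt of the second largest
    # eigenvalue of the GLCM transition form Q
    nz = (px > 0) & (py > 0)
    if nz.sum() >= 2:
        p_nz = p[np.ix_(nz, nz)]
        q = (p_nz[:, None, :] * p_nz[None, :, :] /
             (px[nz][:, None, None] * py[nz][None, None, :])).sum(axis=2)
        eig = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(np.clip(eig[1], 0.0, 1.0))) if eig.size >= 2 else 0.0
    else:
        mcc = 0.0

    return np.array([
        autocorr, contrast, correlation, cluster_prom, cluster_shade,
        dissimilarity, asm, entropy, homogeneity, max_prob, sum_squares,
        sum_avg, sum_entropy, sum_var, diff_var, diff_entropy, imc1, imc2,
        inv_diff, inv_diff_norm, inv_moment_norm, mcc,
    ])


def gtf_features(roi_pixels: np.ndarray, config: GLCMConfig | None = None) -> np.ndarray:
    """88 GLCM descriptors: the 22 per-angle values concatenated
    angle-major (all 22 at 0°, then 45°, 90°, 135°)."""
    config = config or GLCMConfig()
    blocks = [haralick_descriptors(glcm(roi_pixels, config, a)) for a in config.angles]
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# TEF — wavelet subband energies

TEF_MIN_SIDE = 16
_WAVELET = "db2"
_LEVELS = 4


def tef_features(roi_pixels: np.ndarray) -> np.ndarray:
    """13 relative wavelet energies of a 4-level Daubechies-2
    decomposition: H, V, D details at levels 1–4 plus the level-4
    approximation. Sum to 1 for any nonzero ROI."""
    roi_pixels = np.asarray(roi_pixels, dtype=np.float64)
    if min(roi_pixels.shape) < TEF_MIN_SIDE:
        raise ValueError(
            f"ROI must be at least {TEF_MIN_SIDE}x{TEF_MIN_SIDE} for a "
            f"{_LEVELS}-level decomposition; got {roi_pixels.shape}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # boundary-effect notice
        coeffs = pywt.wavedec2(roi_pixels, _WAVELET, level=_LEVELS, mode="reflect")
    approx = coeffs[0]
    details = coeffs[1:]  # coarse (level 4) ... fine (level 1)
    energies = []
    for level_bands in reversed(details):  # level 1 first
        energies.extend(float((b**2).sum()) for b in level_bands)
    energies.append(float((approx**2).sum()))
    energies = np.array(energies)
    total = energies.sum()
    if total == 0:
        # all-zero ROI: put unit weight on the approximation by convention
        out = np.zeros(13)
        out[-1] = 1.0
        return out
    return energies / total


# ---------------------------------------------------------------------------
# combined vector


def _masked_bbox(roi_pixels: np.ndarray, mask: np.ndarray, min_side: int) -> np.ndarray:
    """Masked ROI cropped to the mask bounding box, expanded (within the
    ROI) to at least min_side on each axis."""
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1

    def expand(lo, hi, size):
        while hi - lo < min_side and (lo > 0 or hi < size):
            if lo > 0:
                lo -= 1
            if hi - lo < min_side and hi < size:
                hi += 1
        return lo, hi

    r0, r1 = expand(r0, r1, mask.shape[0])
    c0, c1 = expand(c0, c1, mask.shape[1])
    return np.where(mask, roi_pixels, 0.0)[r0:r1, c0:c1]


def extract_all(roi_pixels: np.ndarray, nodule_mask: np.ndarray,
                glcm_config: GLCMConfig | None = None) -> FeatureVector:
    """Full 123-element vector for one segmented nodule.

    SSF is computed on the intensities inside the mask, SBF on the mask
    itself, GTF and TEF on the masked ROI cropped to the mask bounding
    box (expanded to 16 px minimum for the wavelet decomposition).
    """
    glcm_config = glcm_config or GLCMConfig()
    roi_pixels = np.asarray(roi_pixels, dtype=np.float64)
    nodule_mask = as_mask(nodule_mask)
    if roi_pixels.shape != nodule_mask.shape:
        raise ValueError("ROI and mask shapes differ")
    try:
        ssf = ssf_features(roi_pixels[nodule_mask])
    except ValueError as e:
        raise ValueError(f"SSF failed: {e}") from e
    try:
        sbf = sbf_features(nodule_mask)
    except ValueError as e:
        raise ValueError(f"SBF failed: {e}") from e
    crop = _masked_bbox(roi_pixels, nodule_mask, TEF_MIN_SIDE)
    try:
        gtf = gtf_features(crop, glcm_config)
    except ValueError as e:
        raise ValueError(f"GTF failed: {e}") from e
    try:
        tef = tef_features(crop)
    except ValueError as e:
        raise ValueError(f"TEF failed: {e}") from e
    names = SSF_NAMES + SBF_NAMES + _gtf_names(glcm_config.angles) + TEF_NAMES
    return FeatureVector(values=np.concatenate([ssf, sbf, gtf, tef]), names=names)
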