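"""Candidate nodule detection with the circular Hough transform (CHT).

Nodules are roughly circular, so circle evidence is accumulated from the
edge map of the lung-masked slice over a discrete radius grid. Three
radius search bands cover the clinical size spectrum: 3–12 mm, 10–20 mm
and 15–45 mm. Accumulator scores are normalized by circle perimeter, so
a score of 1.0 means a complete circle of edge pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle

from lucad.imaging import CTSlice, as_mask

#: Canonical radius search bands, millimetres.
BANDS = {
    "small": (3.0, 12.0),
    "medium": (10.0, 20.0),
    "large": (15.0, 45.0),
}


@dataclass(frozen=True)
class RadiusBand:
    """A named radius search range in millimetres."""

    name: str
    min_mm: float
    max_mm: float

    def __post_init__(self) -> None:
        if not (0 < self.min_mm < self.max_mm):
            raise ValueError("need 0 < min_mm < max_mm")

    @classmethod
    def named(cls, name: str) -> "RadiusBand":
        return cls(name, *BANDS[name])

    def radii_px(self, pixel_spacing_mm: float) -> np.ndarray:
        """Integer pixel radii spanning the band, rounded outward so no
        band collapses by truncation."""
        lo = max(1, int(np.floor(self.min_mm / pixel_spacing_mm)))
        hi = int(np.ceil(self.max_mm / pixel_spacing_mm))
        if hi < 1:
            raise ValueError(
                f"band {self.name} collapses to zero radius at spacing {pixel_spacing_mm} mm"
            )
        return np.arange(lo, hi + 1)


@dataclass
class CandidateNodule:
    """A circle hypothesis from the CHT accumulator."""

    center_rc: tuple[int, int]
    radius_px: float
    radius_mm: float
    score: float
    band: str = ""


@dataclass
class ChtParams:
    """Detection tuning.

    score_threshold : minimum perimeter-normalized accumulator value
        (1.0 = full circle of edge pixels present).
    canny_sigma : Gaussian scale of the edge detector.
    min_center_dist_px : suppression distance between kept candidates.
    max_peaks_per_radius : accumulator peaks examined per radius.
    """

    score_threshold: float = 0.3
    canny_sigma: float = 2.0
    min_center_dist_px: float = 5.0
    max_peaks_per_radius: int = 10


def _edge_map(ct: CTSlice, lung_mask: np.ndarray, sigma: float) -> np.ndarray:
    edges = canny(ct.pixels, sigma=sigma)
    return edges & lung_mask


def cht_detect(ct: CTSlice, lung_mask: np.ndarray, band: RadiusBand,
               params: ChtParams | None = None) -> list[CandidateNodule]:
    """Detect circle candidates in one radius band, centers restricted to
    the lung mask. Returns candidates sorted by descending score."""
    params = params or ChtParams()
    lung_mask = as_mask(lung_mask)
    if lung_mask.shape != ct.shape:
        raise ValueError("lung mask shape does not match slice")
    if not lung_mask.any():
        return []
    radii = band.radii_px(ct.pixel_spacing_mm)
    edges = _edge_map(ct, lung_mask, params.canny_sigma)
    if not edges.any():
        return []
    accum = hough_circle(edges, radii)  # perimeter-normalized scores

    cands: list[CandidateNodule] = []
    for acc, r in zip(accum, radii):
        # top accumulator peaks for this radius
        flat = acc.ravel()
        k = min(params.max_peaks_per_radius, flat.size)
        idx = np.argpartition(flat, -k)[-k:]
        for i in idx[np.argsort(flat[idx])[::-1]]:
            score = float(flat[i])
            if score < params.score_threshold:
                break
            row, col = np.unravel_index(i, acc.shape)
            if not lung_mask[row, col]:
                continue
            cands.append(CandidateNodule(
                center_rc=(int(row), int(col)),
                radius_px=float(r),
                radius_mm=float(r) * ct.pixel_spacing_mm,
                score=score,
                band=band.name,
            ))
    cands.sort(key=lambda c: (-c.score, c.center_rc, c.radius_px))
    return cands


def nonmax_suppress(cands: list[CandidateNodule],
                    min_center_dist_px: float = 5.0) -> list[CandidateNodule]:
    """Greedy suppression on a score-sorted candidate list: keep a
    candidate iff its center is at least the suppression distance from
    every already-kept center. The per-pair distance is the larger of
    `min_center_dist_px` and the smaller radius of the pair, so big
    circles suppress their own off-center echoes. Stable, deterministic."""
    kept: list[CandidateNodule] = []
    for c in cands:
        near = any(
            np.hypot(c.center_rc[0] - k.center_rc[0],
                     c.center_rc[1] - k.center_rc[1])
            < max(min_center_dist_px, min(c.radius_px, k.radius_px))
            for k in kept
        )
        if not near:
            kept.append(c)
    return kept


def detect_all_bands(ct: CTSlice, lung_mask: np.ndarray,
                     params: ChtParams | None = None) -> list[CandidateNodule]:
    """Union of per-band detections followed by global suppression; each
    surviving candidate keeps the name of the band that produced it."""
    params = params or ChtParams()
    merged: list[CandidateNodule] = []
    for name in ("small", "medium", "large"):
        merged.extend(cht_detect(ct, lung_mask, RadiusBand.named(name), params))
    merged.sort(key=lambda c: (-c.score, c.center_rc, c.radius_px))
    return nonmax_suppress(merged, params.min_center_dist_px)
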