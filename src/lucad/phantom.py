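"""Seeded synthetic chest-CT phantom with full ground truth.

The generator stands in for a private clinical dataset: each slice is a
bright body ellipse on dark background air, containing two dark
elliptical lung fields, a handful of bright vessel segments, and zero or
more circular nodules with known masks, diameters and benign/malign
labels.

Malignancy is encoded through the two cues that distinguish the classes
radiologically and statistically: benign nodules are rendered as round
disks with a smooth (Gaussian-feathered) edge and low internal intensity
noise, while malign nodules get a radially perturbed star-convex
boundary (spiculation: >= 8 random harmonics scaled by a relative
amplitude) and higher internal noise variance. Everything is driven by a
single integer seed, and identical (spec, seed) pairs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from lucad.imaging import CTSlice, write_mask

BENIGN, MALIGN = "benign", "malign"

#: Default per-band nodule counts emulating the reference cohort:
#: 220 nodules split 75 / 65 / 80 across <10 / 10–20 / >20 mm.
DEFAULT_SIZE_BINS = (75, 65, 80)
DEFAULT_N_BENIGN = 104
DEFAULT_N_MALIGN = 116

#: Sampling ranges (diameter, mm) for the three size bands.
BAND_RANGES = {"<10": (4.0, 10.0), "10-20": (10.0, 20.0), ">20": (20.0, 40.0)}


@dataclass
class PhantomSpec:
    """Rendering parameters of one synthetic slice.

    Intensity levels are on the raw [0, 1] scale before enhancement:
    background air ~0.05, body soft tissue ~0.75, lung fields ~0.15,
    vessels ~0.6, nodules ~0.55.
    """

    image_size: int = 512
    pixel_spacing_mm: float = 0.7
    n_nodules: int = 2
    size_range_mm: tuple[float, float] = (4.0, 40.0)
    malign_fraction: float = 0.5
    background_level: float = 0.05
    body_level: float = 0.75
    lung_level: float = 0.15
    vessel_level: float = 0.60
    nodule_level: float = 0.55
    lung_texture_std: float = 0.02
    benign_noise_std: float = 0.01
    malign_noise_std: float = 0.06
    spiculation_amplitude: float = 0.28
    spiculation_harmonics: int = 10
    pixel_noise_std: float = 0.01
    n_vessels_range: tuple[int, int] = (5, 15)

    def __post_init__(self) -> None:
        lo, hi = self.size_range_mm
        if not (3.0 <= lo < hi <= 65.0):
            raise ValueError("nodule diameters must stay within [3, 65] mm")
        if not (0.0 <= self.malign_fraction <= 1.0):
            raise ValueError("malign_fraction must be in [0, 1]")


@dataclass
class NoduleTruth:
    mask: np.ndarray
    center_rc: tuple[int, int]
    diameter_mm: float
    label: str
    band: str = field(default="")

    def __post_init__(self) -> None:
        if not self.band:
            d = self.diameter_mm
            self.band = "<10" if d < 10 else ("10-20" if d <= 20 else ">20")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) / semi[0]) ** 2 +
            ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _lung_geometry(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Left and right lung-field masks for an n×n slice."""
    left = _ellipse_mask((n, n), (0.50 * n, 0.32 * n), (0.30 * n, 0.16 * n))
    right = _ellipse_mask((n, n), (0.50 * n, 0.68 * n), (0.30 * n, 0.16 * n))
    return left, right


def _spiculated_mask(shape: tuple[int, int], center: tuple[int, int],
                     radius_px: float, amplitude: float, harmonics: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Star-convex mask: boundary radius r(θ) = r (1 + amplitude·s(θ)),
    s a zero-mean sum of >= 8 random-phase harmonics normalized to
    max |s| = 1."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    theta = np.arctan2(dy, dx)
    s = np.zeros_like(theta, dtype=np.float64)
    for k in range(2, 2 + harmonics):
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.3, 1.0)
        s = s + weight * np.cos(k * theta + phase)
    s = s / np.max(np.abs(s))
    r_theta = radius_px * (1.0 + amplitude * s)
    return np.hypot(dy, dx) <= r_theta


def make_slice(spec: PhantomSpec, seed: int,
               nodules: list[tuple[float, str]] | None = None
               ) -> tuple[CTSlice, np.ndarray, list[NoduleTruth]]:
    """Render one phantom slice.

    Parameters
    ----------
    spec : rendering parameters.
    seed : RNG seed; identical (spec, seed, nodules) → identical output.
    nodules : optional explicit list of (diameter_mm, label); when None,
        ``spec.n_nodules`` nodules are sampled from ``spec.size_range_mm``
        with ``spec.malign_fraction``.

    Returns
    -------
    (slice, lung_truth, nodule_truths) — nodule masks are pairwise
    disjoint and contained in the lung truth.
    """
    rng = np.random.default_rng(seed)
    n = spec.image_size
    img = np.full((n, n), spec.background_level)

    body = _ellipse_mask((n, n), (0.52 * n, 0.50 * n), (0.44 * n, 0.46 * n))
    img[body] = spec.body_level
    left, right = _lung_geometry(n)
    lung_truth = left | right
    img[lung_truth] = spec.lung_level
    img[lung_truth] += rng.normal(0.0, spec.lung_texture_std, lung_truth.sum())

    # vessels: short thick bright segments inside the lung fields
    interior = ndimage.binary_erosion(lung_truth, iterations=4)
    ir, ic = np.nonzero(interior)
    n_vessels = int(rng.integers(spec.n_vessels_range[0], spec.n_vessels_range[1] + 1))
    for _ in range(n_vessels):
        j = rng.integers(ir.size)
        r0, c0 = ir[j], ic[j]
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.02 * n, 0.08 * n)
        thickness = rng.uniform(1.0, 0.006 * n + 1.0)
        t = np.linspace(0, length, int(length) * 2 + 2)
        pr = np.clip(r0 + t * np.sin(angle), 0, n - 1).astype(int)
        pc = np.clip(c0 + t * np.cos(angle), 0, n - 1).astype(int)
        seg = np.zeros((n, n), bool)
        seg[pr, pc] = True
        seg = ndimage.binary_dilation(seg, iterations=max(1, int(thickness)))
        img[seg & lung_truth] = spec.vessel_level

    if nodules is None:
        n_mal = int(round(spec.n_nodules * spec.malign_fraction))
        labels = [MALIGN] * n_mal + [BENIGN] * (spec.n_nodules - n_mal)
        nodules = [(float(rng.uniform(*spec.size_range_mm)), lab) for lab in labels]

    # placement: centers where the (slightly padded) nodule fits inside
    # the lungs and does not overlap an earlier nodule
    dist_in = ndimage.distance_transform_edt(lung_truth)
    truths: list[NoduleTruth] = []
    occupied = np.zeros((n, n), bool)
    for diameter_mm, label in nodules:
        radius_px = diameter_mm / 2.0 / spec.pixel_spacing_mm
        # clearance keeps nodules intraparenchymal (not juxtapleural), so
        # lung extraction retains them as fillable holes
        pad = radius_px * (1.0 + (spec.spiculation_amplitude if label == MALIGN else 0.0)) + 8
        feasible = dist_in > pad
        placed = False
        for _ in range(200):
            fr, fc = np.nonzero(feasible)
            if fr.size == 0:
                break
            j = rng.integers(fr.size)
            r0, c0 = int(fr[j]), int(fc[j])
            if label == MALIGN:
                mask = _spiculated_mask((n, n), (r0, c0), radius_px,
                                        spec.spiculation_amplitude,
                                        spec.spiculation_harmonics, rng)
            else:
                mask = _ellipse_mask((n, n), (r0, c0), (radius_px, radius_px))
            if (mask & occupied).any() or not (mask <= lung_truth).all():
                continue
            noise_std = spec.malign_noise_std if label == MALIGN else spec.benign_noise_std
            target = np.full((n, n), spec.nodule_level)
            target[mask] += rng.normal(0.0, noise_std, int(mask.sum()))
            alpha = mask.astype(np.float64)
            if label == BENIGN:
                # smooth, well-defined border: feather outward only, so the
                # interior keeps its (low) noise variance intact
                alpha = np.maximum(alpha, ndimage.gaussian_filter(alpha, sigma=1.0))
            img = img * (1.0 - alpha) + target * alpha
            occupied |= ndimage.binary_dilation(mask, iterations=3)
            truths.append(NoduleTruth(mask=mask, center_rc=(r0, c0),
                                      diameter_mm=float(diameter_mm), label=label))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {diameter_mm:.1f} mm {label} nodule; "
                "use fewer or smaller nodules for this slice size"
            )

    img = img + rng.normal(0.0, spec.pixel_noise_std, (n, n))
    ct = CTSlice(pixels=np.clip(img, 0.0, 1.0),
                 pixel_spacing_mm=spec.pixel_spacing_mm,
                 slice_id=f"phantom-{seed}")
    return ct, lung_truth, truths


def _band_of(diameter: float) -> str:
    return "<10" if diameter < 10 else ("10-20" if diameter <= 20 else ">20")


def make_dataset(n_benign: int = DEFAULT_N_BENIGN, n_malign: int = DEFAULT_N_MALIGN,
                 size_bins: tuple[int, int, int] = DEFAULT_SIZE_BINS,
                 seed: int = 0, spec: PhantomSpec | None = None,
                 nodules_per_slice: int = 2, out_dir: str | Path | None = None
                 ) -> tuple[pd.DataFrame, list[tuple[CTSlice, np.ndarray, list[NoduleTruth]]]]:
    """Generate a labeled phantom dataset.

    Nodule diameters are sampled per size band (counts `size_bins` over
    <10 / 10–20 / >20 mm, which must sum to ``n_benign + n_malign``);
    labels are assigned by interleaving benign/malign across the shuffled
    size list so both classes span all bands. Slices hold
    `nodules_per_slice` nodules each.

    Returns the manifest (one row per nodule) and the rendered slices;
    when `out_dir` is given, slice and mask PNGs are also written and the
    manifest includes their paths.
    """
    spec = spec or PhantomSpec()
    total = n_benign + n_malign
    if sum(size_bins) != total:
        raise ValueError(f"size_bins {size_bins} must sum to {total}")
    rng = np.random.default_rng(seed)

    diameters: list[float] = []
    for count, band in zip(size_bins, ("<10", "10-20", ">20")):
        if count == 0:
            continue
        lo, hi = BAND_RANGES[band]
        hi = min(hi, spec.size_range_mm[1])
        lo = max(lo, spec.size_range_mm[0])
        diameters.extend(rng.uniform(lo, hi, count))
    order = rng.permutation(total)
    diameters = [diameters[i] for i in order]
    labels = np.array([BENIGN] * n_benign + [MALIGN] * n_malign)
    labels = labels[rng.permutation(total)]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows, rendered = [], []
    for start in range(0, total, nodules_per_slice):
        chunk = [(diameters[i], str(labels[i])) for i in
                 range(start, min(start + nodules_per_slice, total))]
        # larger nodules placed first so they still fit
        chunk.sort(key=lambda t: -t[0])
        slice_seed = int(rng.integers(0, 2**31 - 1))
        ct, lung_truth, truths = make_slice(spec, slice_seed, nodules=chunk)
        ct.slice_id = f"phantom-{start // nodules_per_slice:04d}"
        rendered.append((ct, lung_truth, truths))
        for k, t in enumerate(truths):
            row = {
                "slice_id": ct.slice_id, "nodule_id": f"{ct.slice_id}-n{k}",
                "row": t.center_rc[0], "col": t.center_rc[1],
                "diameter_mm": round(t.diameter_mm, 3), "band": t.band,
                "label": t.label, "slice_seed": slice_seed,
            }
            rows.append(row)
        if out_dir is not None:
            import imageio.v3 as iio
            img16 = (ct.pixels * 65535).astype(np.uint16)
            iio.imwrite(out_dir / f"{ct.slice_id}.png", img16)
            write_mask(lung_truth, out_dir / f"{ct.slice_id}_lung.png")
            for k, t in enumerate(truths):
                write_mask(t.mask, out_dir / f"{ct.slice_id}_n{k}.png")

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest["slice_file"] = manifest["slice_id"] + ".png"
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, rendered
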