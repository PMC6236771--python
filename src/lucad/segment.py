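"""Nodule segmentation with a self-organizing map (SOM).

Each candidate circle gets a square region of interest (ROI); a small 1D
SOM is trained on the ROI's own pixels (unsupervised, per-ROI), pixels
are assigned to their nearest prototype, and the nodule is taken as the
brightest cluster overlapping the candidate center, reduced to one
connected component with holes filled. Per-ROI training keeps very small
nodules segmentable: the map adapts to local contrast instead of a
global intensity model.

The pixel feature is 2D — (intensity, 3×3 local mean intensity) — so the
clustering sees both the pixel and a little of its neighbourhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from lucad.detect import CandidateNodule
from lucad.imaging import CTSlice

MIN_ROI_SIDE = 9


@dataclass
class SOMConfig:
    """Training schedule of the 1D SOM.

    n_nodes : map units on the chain (default 4: background, parenchyma
        texture, vessel/edge, nodule).
    epochs : full passes over the training samples.
    lr_initial, lr_final : exponential learning-rate schedule endpoints.
    neighborhood_initial, neighborhood_final : Gaussian neighbourhood
        radius endpoints, in map units.
    """

    n_nodes: int = 4
    epochs: int = 20
    lr_initial: float = 0.5
    lr_final: float = 0.01
    neighborhood_initial: float = 2.0
    neighborhood_final: float = 0.1

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.lr_final <= self.lr_initial <= 1):
            raise ValueError("need 0 < lr_final <= lr_initial <= 1")


@dataclass
class NoduleROI:
    """Square sub-image around a candidate, side = 2*ceil(1.5*radius)+1
    (clamped to at least 9 px and shifted to fit inside the slice)."""

    pixels: np.ndarray
    origin_rc: tuple[int, int]
    candidate: CandidateNodule

    @property
    def center_in_roi(self) -> tuple[int, int]:
        return (self.candidate.center_rc[0] - self.origin_rc[0],
                self.candidate.center_rc[1] - self.origin_rc[1])


def extract_roi(ct: CTSlice, candidate: CandidateNodule,
                min_side: int = MIN_ROI_SIDE) -> NoduleROI:
    """Cut the ROI for a candidate, shifting it inward at image borders."""
    h, w = ct.shape
    side = max(min_side, 2 * int(np.ceil(1.5 * candidate.radius_px)) + 1)
    if side > min(h, w):
        raise ValueError(f"ROI side {side} exceeds slice extent {min(h, w)}")
    r, c = candidate.center_rc
    half = side // 2
    r0 = int(np.clip(r - half, 0, h - side))
    c0 = int(np.clip(c - half, 0, w - side))
    return NoduleROI(pixels=ct.pixels[r0:r0 + side, c0:c0 + side].copy(),
                     origin_rc=(r0, c0), candidate=candidate)


class SOMSegmenter(BaseEstimator, ClusterMixin):
    """Classic online SOM on a 1D node chain, scikit-learn style.

    Parameters mirror :class:`SOMConfig`. ``fit`` learns the prototype
    vectors from sample rows; ``predict`` assigns each row to its nearest
    prototype (Euclidean).

    Attributes
    ----------
    weights_ : ndarray, shape (n_nodes, n_features)
        Learned prototype vectors.
    """

    def __init__(self, n_nodes: int = 4, epochs: int = 20, lr_initial: float = 0.5,
                 lr_final: float = 0.01, neighborhood_initial: float = 2.0,
                 neighborhood_final: float = 0.1, random_state: int = 0):
        self.n_nodes = n_nodes
        self.epochs = epochs
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.neighborhood_initial = neighborhood_initial
        self.neighborhood_final = neighborhood_final
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "SOMSegmenter":
        cfg = SOMConfig(self.n_nodes, self.epochs, self.lr_initial, self.lr_final,
                        self.neighborhood_initial, self.neighborhood_final)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D (samples x features)")
        if X.shape[0] < cfg.n_nodes:
            raise ValueError(f"need at least {cfg.n_nodes} samples, got {X.shape[0]}")
        rng = np.random.default_rng(self.random_state)

        # init: sample n_nodes training vectors, ordered by first feature
        # so the chain starts roughly intensity-sorted
        init_idx = rng.choice(X.shape[0], size=cfg.n_nodes, replace=False)
        w = X[init_idx].copy()
        w = w[np.argsort(w[:, 0], kind="stable")]

        node_pos = np.arange(cfg.n_nodes, dtype=np.float64)
        n_steps = cfg.epochs * X.shape[0]
        lr_decay = np.log(cfg.lr_final / cfg.lr_initial)
        nb_decay = np.log(self.neighborhood_final / self.neighborhood_initial)
        step = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(X.shape[0])
            for i in order:
                frac = step / max(1, n_steps - 1)
                lr = cfg.lr_initial * np.exp(lr_decay * frac)
                nb = self.neighborhood_initial * np.exp(nb_decay * frac)
                x = X[i]
                winner = int(np.argmin(((w - x) ** 2).sum(axis=1)))
                h = np.exp(-((node_pos - winner) ** 2) / (2.0 * nb * nb))
                w += lr * h[:, None] * (x - w)
                step += 1
        self.weights_ = w
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimensionality does not match fit")
        d2 = ((X[:, None, :] - self.weights_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def pixel_features(roi_pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature rows: (intensity, 3x3 mean intensity)."""
    local = ndimage.uniform_filter(roi_pixels, size=3, mode="reflect")
    return np.column_stack([roi_pixels.ravel(), local.ravel()])


def som_train(samples: np.ndarray, config: SOMConfig | None = None,
              seed: int = 0) -> SOMSegmenter:
    """Train a SOM on sample feature rows; thin wrapper over SOMSegmenter."""
    config = config or SOMConfig()
    model = SOMSegmenter(
        n_nodes=config.n_nodes, epochs=config.epochs,
        lr_initial=config.lr_initial, lr_final=config.lr_final,
        neighborhood_initial=config.neighborhood_initial,
        neighborhood_final=config.neighborhood_final, random_state=seed,
    )
    return model.fit(np.asarray(samples, dtype=np.float64))


def som_segment(roi: NoduleROI, model: SOMSegmenter
                ) -> tuple[np.ndarray, np.ndarray]:
    """Assign ROI pixels to SOM clusters and cut out the nodule mask.

    The nodule cluster is the node with the highest mean intensity among
    nodes whose region overlaps a small window around the candidate
    center (falling back to the globally brightest cluster); the mask is
    the connected component of that cluster at/nearest the ROI center,
    with holes filled.

    Returns ``(label_map, nodule_mask)``.
    """
    feats = pixel_features(roi.pixels)
    labels = model.predict(feats).reshape(roi.pixels.shape)

    if np.unique(roi.pixels).size == 1:
        warnings.warn("uniform ROI: degenerate segmentation", stacklevel=2)
        return labels, np.zeros_like(roi.pixels, dtype=bool)

    cr, cc = roi.center_in_roi
    cr = int(np.clip(cr, 0, roi.pixels.shape[0] - 1))
    cc = int(np.clip(cc, 0, roi.pixels.shape[1] - 1))
    # clusters present in a 3x3 window around the candidate center
    r0, r1 = max(0, cr - 1), min(roi.pixels.shape[0], cr + 2)
    c0, c1 = max(0, cc - 1), min(roi.pixels.shape[1], cc + 2)
    center_clusters = np.unique(labels[r0:r1, c0:c1])

    means = np.array([
        roi.pixels[labels == k].mean() if np.any(labels == k) else -np.inf
        for k in range(model.weights_.shape[0])
    ])
    nodule_cluster = int(center_clusters[np.argmax(means[center_clusters])])

    # merge edge clusters: any cluster whose mean intensity is closer to
    # the nodule cluster's than to the darkest cluster's belongs to the
    # nodule (boundary pixels form their own mixed cluster otherwise)
    darkest = means[np.isfinite(means)].min()
    members = [
        k for k in range(means.size)
        if np.isfinite(means[k])
        and abs(means[k] - means[nodule_cluster]) < abs(means[k] - darkest)
    ] or [nodule_cluster]
    cluster_mask = np.isin(labels, members)
    comp_labels, n_comp = ndimage.label(cluster_mask,
                                        structure=ndimage.generate_binary_structure(2, 2))
    if n_comp == 0:
        warnings.warn("nodule cluster empty in ROI", stacklevel=2)
        return labels, np.zeros_like(cluster_mask)
    if comp_labels[cr, cc] > 0:
        chosen = comp_labels[cr, cc]
    else:
        # nearest component to the ROI center
        dists = ndimage.distance_transform_edt(comp_labels == 0,
                                               return_indices=True)[1]
        chosen = comp_labels[dists[0][cr, cc], dists[1][cr, cc]]
    mask = ndimage.binary_fill_holes(comp_labels == chosen)
    return labels, mask


def segment_candidate(ct: CTSlice, candidate: CandidateNodule,
                      config: SOMConfig | None = None, seed: int = 0
                      ) -> tuple[NoduleROI, np.ndarray]:
    """End-to-end per-candidate segmentation: ROI cut, per-ROI SOM train,
    cluster assignment, nodule mask."""
    roi = extract_roi(ct, candidate)
    model = som_train(pixel_features(roi.pixels), config, seed=seed)
    _, mask = som_segment(roi, model)
    return roi, mask
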