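"""PCA feature reduction with the class-size component rule.

The number of retained components follows the pattern-count heuristic:
at most one third of the training patterns in the smaller class, i.e.
``floor(min_class_size * split_fraction / 3)`` (at least 1). With the
reference class sizes — smallest class 104 patterns and a half split —
the rule retains 17 of the 123 features.

Features mix incommensurate units (px², bits, ratios), so columns are
standardized to zero mean / unit variance before the eigendecomposition;
component signs are fixed so each loading's largest-magnitude entry is
positive, making fits bit-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted


def n_components_rule(min_class_size: int, split_fraction: float = 0.5) -> int:
    """Components retained: floor(min_class_size * split_fraction / 3), >= 1."""
    if min_class_size < 3:
        raise ValueError("min_class_size must be >= 3")
    if not (0 < split_fraction <= 1):
        raise ValueError("split_fraction must be in (0, 1]")
    return max(1, int(np.floor(min_class_size * split_fraction / 3.0)))


class PCAReducer(BaseEstimator, TransformerMixin):
    """Standardize-then-PCA reducer with deterministic component signs.

    Parameters
    ----------
    n_components : int
        Components to retain (use :func:`n_components_rule` to derive it
        from class sizes).

    Attributes
    ----------
    feature_means_, feature_scales_ : ndarray, shape (n_features,)
        Standardization parameters (zero-variance columns get scale 1).
    loadings_ : ndarray, shape (n_components, n_features)
        Orthonormal component directions, variance-ordered.
    explained_variance_ : ndarray, shape (n_components,)
        Per-component variance, nonincreasing.
    """

    def __init__(self, n_components: int = 17):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "PCAReducer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if X.shape[0] < self.n_components + 1:
            raise ValueError(
                f"need at least n_components+1={self.n_components + 1} rows, "
                f"got {X.shape[0]}"
            )
        rank = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank {rank}")
        scaler = StandardScaler().fit(X)
        # zero-variance columns pass through with scale 1
        scaler.scale_ = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        Z = scaler.transform(X)
        pca = PCA(n_components=self.n_components, svd_solver="full").fit(Z)
        loadings = pca.components_
        # sign convention: largest-|.| entry of each loading positive
        for k in range(loadings.shape[0]):
            j = int(np.argmax(np.abs(loadings[k])))
            if loadings[k, j] < 0:
                loadings[k] = -loadings[k]
        self.feature_means_ = scaler.mean_
        self.feature_scales_ = scaler.scale_
        self.loadings_ = loadings
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was fit with {self.n_features_in_}"
            )
        Z = (X - self.feature_means_) / self.feature_scales_
        return Z @ self.loadings_.T

    # -- JSON serialization for reproducible reuse ---------------------------

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "loadings_")
        payload = {
            "n_components": self.n_components,
            "feature_means": self.feature_means_.tolist(),
            "feature_scales": self.feature_scales_.tolist(),
            "loadings": self.loadings_.tolist(),
            "explained_variance": self.explained_variance_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAReducer":
        payload = json.loads(Path(path).read_text())
        model = cls(n_components=payload["n_components"])
        model.feature_means_ = np.array(payload["feature_means"])
        model.feature_scales_ = np.array(payload["feature_scales"])
        model.loadings_ = np.array(payload["loadings"])
        model.explained_variance_ = np.array(payload["explained_variance"])
        model.n_features_in_ = model.loadings_.shape[1]
        return model


def pca_fit(X: np.ndarray, n_components: int) -> PCAReducer:
    """Fit a standardized PCA model; thin wrapper over PCAReducer."""
    return PCAReducer(n_components=n_components).fit(X)


def pca_transform(model: PCAReducer, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto a fitted model's retained components."""
    return model.transform(X)
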