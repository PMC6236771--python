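"""Probabilistic neural network (PNN) benign/malign classifier.

A PNN is a Parzen-window kernel density classifier: the pattern layer
stores one unit per training example, and the summation layer averages
Gaussian kernels per class,

    score_c(x) = mean_{p in class c} exp(-||x - p||^2 / (2 sigma^2)),

with the posterior obtained by normalizing the class scores. Averaging
(rather than summing) makes the scores prior-free, so an imbalanced
training set does not dominate through pattern count alone; a
prior-weighted variant is available via ``class_weight='prior'``.

There is no iterative training; `sigma` is the only free parameter. With
``sigma='auto'`` it is chosen by maximizing leave-one-out accuracy on
the training set over a logarithmic grid (ties go to the smaller sigma).

On an exact posterior tie the benign label wins: the deliberate
convention is to favour the non-cancer call only when the evidence is
perfectly balanced.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted

BENIGN, MALIGN = "benign", "malign"

#: Log-spaced sigma grid searched by sigma='auto'.
SIGMA_GRID = np.logspace(np.log10(0.05), np.log10(5.0), 10)


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Parzen-window PNN for two-class problems, scikit-learn style.

    Parameters
    ----------
    sigma : float or 'auto'
        Gaussian kernel spread. 'auto' selects from ``SIGMA_GRID`` by
        leave-one-out training accuracy.
    class_weight : 'uniform' or 'prior'
        'uniform' averages kernels within each class (equal priors);
        'prior' sums them (class scores carry training prevalence).

    Attributes
    ----------
    patterns_ : ndarray (n_samples, n_features)
        Stored training vectors (the pattern layer).
    pattern_labels_ : ndarray (n_samples,)
        Class of each stored pattern.
    sigma_ : float
        The spread actually used (resolved when sigma='auto').
    classes_ : ndarray
        Sorted class labels.
    """

    def __init__(self, sigma: float | str = "auto", class_weight: str = "uniform"):
        self.sigma = sigma
        self.class_weight = class_weight

    def fit(self, X: np.ndarray, y) -> "PNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2D with one label per row")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if self.class_weight not in ("uniform", "prior"):
            raise ValueError("class_weight must be 'uniform' or 'prior'")
        self.classes_ = classes
        self.patterns_ = X.copy()
        self.pattern_labels_ = y.copy()
        self.n_features_in_ = X.shape[1]
        if self.sigma == "auto":
            self.sigma_ = self._select_sigma(X, y)
        else:
            if not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
                raise ValueError("sigma must be positive or 'auto'")
            self.sigma_ = float(self.sigma)
        return self

    def _class_scores(self, X: np.ndarray, patterns: np.ndarray,
                      labels: np.ndarray, sigma: float) -> np.ndarray:
        d2 = pairwise_distances(X, patterns, metric="sqeuclidean")
        k = np.exp(-d2 / (2.0 * sigma * sigma))
        agg = np.mean if self.class_weight == "uniform" else np.sum
        return np.column_stack([
            agg(k[:, labels == c], axis=1) for c in self.classes_
        ])

    def _select_sigma(self, X: np.ndarray, y: np.ndarray) -> float:
        """Leave-one-out accuracy over the sigma grid; smallest best sigma."""
        n = X.shape[0]
        best_sigma, best_acc = float(SIGMA_GRID[0]), -1.0
        d2 = pairwise_distances(X, metric="sqeuclidean")
        for sigma in SIGMA_GRID:
            k = np.exp(-d2 / (2.0 * sigma * sigma))
            np.fill_diagonal(k, 0.0)
            scores = np.empty((n, self.classes_.size))
            for c_idx, c in enumerate(self.classes_):
                member = y == c
                denom = member.sum() - member  # excludes self for own class
                s = k[:, member].sum(axis=1)
                if self.class_weight == "uniform":
                    s = s / np.maximum(denom, 1)
                scores[:, c_idx] = s
            pred = self.classes_[self._argmax_with_tie(scores)]
            acc = float(np.mean(pred == y))
            if acc > best_acc:
                best_acc, best_sigma = acc, float(sigma)
        return best_sigma

    def _argmax_with_tie(self, scores: np.ndarray) -> np.ndarray:
        """Argmax over class scores; exact ties resolve to the benign
        class when present, else to the first class in sorted order."""
        idx = np.argmax(scores, axis=1)
        tie = scores.max(axis=1, keepdims=True) == scores
        multi = tie.sum(axis=1) > 1
        if multi.any():
            benign_idx = int(np.argmin(self.classes_ != BENIGN)) \
                if BENIGN in self.classes_ else 0
            idx = np.where(multi & tie[:, benign_idx], benign_idx, idx)
        return idx

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "patterns_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with {self.n_features_in_}"
            )
        scores = self._class_scores(X, self.patterns_, self.pattern_labels_, self.sigma_)
        totals = scores.sum(axis=1, keepdims=True)
        # all kernels underflow: fall back to a flat posterior
        flat = np.full_like(scores, 1.0 / scores.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            proba = np.where(totals > 0, scores / np.where(totals > 0, totals, 1.0), flat)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        return self.classes_[self._argmax_with_tie(proba)]


def pnn_fit(X: np.ndarray, y, sigma: float | str = "auto") -> PNNClassifier:
    """Fit (store) a PNN; thin wrapper over PNNClassifier."""
    return PNNClassifier(sigma=sigma).fit(X, y)


def pnn_predict(model: PNNClassifier, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Predict one vector; returns (label, posterior over model.classes_)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    label = model.predict(x)[0]
    posterior = model.predict_proba(x)[0]
    return label, posterior
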