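"""Performance evaluation: confusion matrices, the six derived criteria,
ROC/AUC, leave-one-out cross-validation and size-stratified reports.

The positive class is *malign* throughout (TP counts malign nodules
predicted malign). The six criteria are

    Acc = 100 (TP+TN)/total          Sen = 100 TP/(TP+FN)
    Spc = 100 TN/(TN+FP)             PDV = 100 TP/(TP+FP)
    NDV = 100 TN/(TN+FN)             F1  = 2TP/(2TP+FP+FN)

with percentages displayed to 2 decimals (round half-up) and full
precision retained internally. A metric with a zero denominator is
reported as None, never as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve, auc as _auc

from lucad.classify import BENIGN, MALIGN, PNNClassifier
from lucad.dimreduce import PCAReducer, n_components_rule

#: Size-band edges in mm: <10, 10–20 (inclusive), >20.
SIZE_BANDS = (("<10", 0.0, 10.0), ("10-20", 10.0, 20.0), (">20", 20.0, np.inf))


def round2(x: float | None) -> float | None:
    """Round half-up to 2 decimals (banker's rounding would disagree with
    printed clinical tables on .005 boundaries)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class PerformanceReport:
    """Full-precision criteria; use :meth:`rounded` for display."""

    acc: float
    sen: float | None
    spc: float | None
    pdv: float | None
    ndv: float | None
    f1: float | None
    auc: float | None = None

    def rounded(self) -> dict:
        out = {k: round2(v) for k, v in
               (("Acc", self.acc), ("Sen", self.sen), ("Spc", self.spc),
                ("PDV", self.pdv), ("NDV", self.ndv), ("F1", self.f1))}
        if self.auc is not None:
            out["AUC"] = round2(self.auc)
        return out


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with malign as the positive class."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for arr in (y_true, y_pred):
        bad = set(np.unique(arr)) - {BENIGN, MALIGN}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == MALIGN) & (y_pred == MALIGN))),
        fp=int(np.sum((y_true == BENIGN) & (y_pred == MALIGN))),
        fn=int(np.sum((y_true == MALIGN) & (y_pred == BENIGN))),
        tn=int(np.sum((y_true == BENIGN) & (y_pred == BENIGN))),
    )


def _ratio(num: int, den: int, scale: float) -> float | None:
    return scale * num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """The six performance criteria of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return PerformanceReport(
        acc=100.0 * (cm.tp + cm.tn) / cm.total,
        sen=_ratio(cm.tp, cm.tp + cm.fn, 100.0),
        spc=_ratio(cm.tn, cm.tn + cm.fp, 100.0),
        pdv=_ratio(cm.tp, cm.tp + cm.fp, 100.0),
        ndv=_ratio(cm.tn, cm.tn + cm.fn, 100.0),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, 1.0),
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR points) and trapezoidal AUC for malign
    posterior scores; equivalent to the normalized Mann–Whitney U."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == MALIGN
    if pos.all() or not pos.any():
        raise ValueError("both classes required for ROC analysis")
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    return np.column_stack([fpr, tpr]), float(_auc(fpr, tpr))


def loocv(X, y, split_fraction: float = 0.5, sigma: float | str = "auto",
          pca_global: bool = False, seed: int = 0
          ) -> tuple[ConfusionMatrix, PerformanceReport, list[dict]]:
    """Nodule-level leave-one-out cross-validation of the PCA+PNN stage.

    Per fold, a PCA reducer (components from the class-size rule applied
    to the training fold) and a PNN are fit on all other nodules and the
    held-out nodule is predicted. ``pca_global=True`` instead fits the
    reducer once on the full table (train+test leakage, for comparison
    with protocols that reduce before validation).

    Returns the pooled confusion matrix, its report (with AUC over the
    pooled malign posteriors), and a per-case log.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 cases each")

    def n_comp_for(labels, n_rows):
        _, c = np.unique(labels, return_counts=True)
        # tiny folds: the rule floor is 1 component
        rule = n_components_rule(max(int(c.min()), 3), split_fraction)
        return min(rule, n_rows - 1, X.shape[1])

    global_reducer = None
    if pca_global:
        global_reducer = PCAReducer(n_components=n_comp_for(y, X.shape[0])).fit(X)

    preds, scores, log = [], [], []
    malign_col = None
    for i in range(X.shape[0]):
        train = np.ones(X.shape[0], dtype=bool)
        train[i] = False
        Xtr, ytr = X[train], y[train]
        if np.unique(ytr).size < 2:
            raise RuntimeError(f"fold {i}: training fold lost a class")
        reducer = global_reducer or PCAReducer(
            n_components=n_comp_for(ytr, Xtr.shape[0])).fit(Xtr)
        clf = PNNClassifier(sigma=sigma).fit(reducer.transform(Xtr), ytr)
        z = reducer.transform(X[i:i + 1])
        label = clf.predict(z)[0]
        proba = clf.predict_proba(z)[0]
        malign_col = int(np.argmax(clf.classes_ == MALIGN))
        preds.append(label)
        scores.append(float(proba[malign_col]))
        log.append({"index": i, "true": str(y[i]), "pred": str(label),
                    "malign_posterior": float(proba[malign_col]),
                    "sigma": clf.sigma_,
                    "n_components": reducer.n_components})
    preds = np.array(preds)
    cm = confusion(y, preds)
    report = metrics(cm)
    _, report.auc = roc_auc(np.array(scores), y)
    return cm, report, log


def size_stratified_report(y_true, y_pred, sizes_mm
                           ) -> dict[str, tuple[ConfusionMatrix, PerformanceReport]]:
    """Per-band confusion matrices and reports, bands <10 / 10–20 / >20 mm
    (10 and 20 inclusive in the middle band), plus the pooled overall row.
    Empty bands are omitted."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    sizes_mm = np.asarray(sizes_mm, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(sizes_mm)):
        raise ValueError("inputs differ in length")
    out: dict[str, tuple[ConfusionMatrix, PerformanceReport]] = {}
    for name, lo, hi in SIZE_BANDS:
        if name == "10-20":
            sel = (sizes_mm >= lo) & (sizes_mm <= hi)
        else:
            sel = (sizes_mm > lo if name == ">20" else sizes_mm >= lo) & (sizes_mm < hi)
        if not sel.any():
            continue
        cm = confusion(y_true[sel], y_pred[sel])
        out[name] = (cm, metrics(cm))
    overall = confusion(y_true, y_pred)
    out["overall"] = (overall, metrics(overall))
    return out
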