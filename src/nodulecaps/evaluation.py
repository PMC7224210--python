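"""Nodule- and patient-level evaluation: confusion metrics, ROC/AUC,
confidence histograms and feature-correlation analysis.

AUC is the area under the empirical ROC curve by trapezoidal integration,
which equals the pairwise concordance probability with ties counted 1/2.
Confidence is the probability the model assigns to its output class, so it
lives in [0.5, 1] for a two-class model; histograms use 10 equal bins over
that range. The feature-correlation analysis mirrors an interpretability
question: do the learned capsule features track clinically meaningful
hand-crafted descriptors (volume, diameter) more than incidental ones
(in-plane center coordinates, which cropped patches cannot see)?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass
class HandCraftedFeatures:
    """Per-nodule descriptors used in the correlation analysis."""

    volume: float
    diameter: float
    x_center: float
    y_center: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.diameter <= 0:
            raise ValueError("volume and diameter must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.volume, self.diameter, self.x_center, self.y_center])


HAND_CRAFTED_NAMES = ("volume", "diameter", "x_center", "y_center")


@dataclass
class EvalReport:
    """Confusion counts, proportions, ROC and per-nodule records."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None     # None when no positives exist
    specificity: float | None     # None when no negatives exist
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    per_nodule: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "roc_points": self.roc_points, "per_nodule": self.per_nodule,
        }


def confusion_metrics(predictions, truths) -> EvalReport:
    """Binary confusion counts and proportions.

    Sensitivity/specificity are ``None`` (flagged undefined) when their
    denominator class is absent.
    """
    y_pred = np.asarray(list(predictions), dtype=int)
    y_true = np.asarray(list(truths), dtype=int)
    if y_pred.shape != y_true.shape or y_pred.ndim != 1 or len(y_pred) == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty 1D lists")
    if not (set(np.unique(y_pred)) <= {0, 1} and set(np.unique(y_true)) <= {0, 1}):
        raise ValueError("predictions and truths must be binary")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y_true),
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
    )


def roc_auc(scores, truths) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC points (fpr, tpr) over all thresholds and trapezoidal AUC."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(truths), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


CONFIDENCE_BINS = np.linspace(0.5, 1.0, 11)


def confidence_histogram(confidences, groups) -> dict[str, np.ndarray]:
    """Histogram model confidences per group over 10 equal bins on [0.5, 1].

    ``groups`` assigns each confidence a group name, typically "benign",
    "malignant" or "indeterminate" (rating-discarded nodules).
    """
    conf = np.asarray(list(confidences), dtype=float)
    groups = list(groups)
    if len(conf) != len(groups):
        raise ValueError("confidences and groups must be equal length")
    if np.any(conf < 0.5 - 1e-12) or np.any(conf > 1.0 + 1e-12):
        raise ValueError("confidences must lie in [0.5, 1]")
    out: dict[str, np.ndarray] = {}
    for g in sorted(set(groups)):
        vals = conf[[i for i, gi in enumerate(groups) if gi == g]]
        out[g], _ = np.histogram(vals, bins=CONFIDENCE_BINS)
    return out


def correlate_features(capsule_features: np.ndarray, hand_crafted: np.ndarray) -> np.ndarray:
    """Pearson correlation of each learned feature with each descriptor.

    Returns an (n_features, n_descriptors) matrix; entries involving a
    constant column are NaN (flagged undefined) rather than an error.
    """
    x = np.asarray(capsule_features, dtype=float)
    h = np.asarray(hand_crafted, dtype=float)
    if x.ndim != 2 or h.ndim != 2 or len(x) != len(h):
        raise ValueError("need (n, p) features and (n, q) descriptors with matching n")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 nodules")
    xc = x - x.mean(axis=0)
    hc = h - h.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    sh = np.sqrt(np.sum(hc**2, axis=0))
    denom = np.outer(sx, sh)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ hc) / denom
    r[denom == 0] = np.nan
    return r


def patient_level_report(per_nodule_predictions, patient_ids, truths) -> EvalReport:
    """Roll nodule predictions up to patients: positive iff any nodule is.

    ``truths`` are per-nodule labels; a patient's true label is likewise
    positive iff any of their nodules is truly malignant.
    """
    preds = list(per_nodule_predictions)
    pids = list(patient_ids)
    y = list(truths)
    if not (len(preds) == len(pids) == len(y)) or len(preds) == 0:
        raise ValueError("need equal-length, non-empty prediction/patient/truth lists")
    by_patient: dict[str, list[tuple[int, int]]] = {}
    for p, pid, t in zip(preds, pids, y):
        by_patient.setdefault(pid, []).append((int(p), int(t)))
    patient_pred = [int(any(p for p, _ in rec)) for rec in by_patient.values()]
    patient_true = [int(any(t for _, t in rec)) for rec in by_patient.values()]
    report = confusion_metrics(patient_pred, patient_true)
    report.per_nodule = [
        {"patient_id": pid, "predicted": pp, "true": pt}
        for pid, pp, pt in zip(by_patient, patient_pred, patient_true)
    ]
    return report
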