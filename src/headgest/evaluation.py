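"""Ground-truth matching, ROC/AUC, and 3-fold cross-validated evaluation.

Detections are compared against mechanical-switch activation times: a
segment is labelled valid when a switch event falls inside it (with a small
temporal tolerance), each switch event labelling at most one segment.  The
classifier score is then swept to trace TPR against FPR; the area under the
ROC curve summarizes each method, reported as mean +/- std over stratified
3-fold cross-validation (folds over segments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .segmentation import Segment
from .threshold import calibrate_threshold, threshold_score
from .hmm import train_hmm_classifier

__all__ = [
    "MATCH_TOLERANCE",
    "SingleClassError",
    "InsufficientPositivesError",
    "RocResult",
    "CrossvalResult",
    "label_segments",
    "roc_auc",
    "crossval_auc",
]

MATCH_TOLERANCE = 0.5  # s, temporal slack when matching switch events to segments


class SingleClassError(ValueError):
    """ROC/AUC is undefined when only one class is present."""


class InsufficientPositivesError(ValueError):
    """A cross-validation fold lacks enough valid segments to train or score."""


def label_segments(
    segments: Sequence[Segment],
    truth_times: np.ndarray | Sequence[float],
    tolerance: float = MATCH_TOLERANCE,
) -> tuple[np.ndarray, int]:
    """Label each segment valid/invalid by temporal matching to switch events.

    A segment is valid iff at least one ground-truth timestamp lies within
    ``[start_t - tolerance, end_t + tolerance]``.  Each truth event labels
    at most one segment — the one whose peak time is nearest (earlier
    segment wins ties).  Returns the boolean labels and the number of truth
    events that matched no segment (missed activations).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    truth_times = np.asarray(truth_times, float)
    labels = np.zeros(len(segments), bool)
    missed = 0
    for ts in truth_times:
        best = None
        best_dist = np.inf
        for i, seg in enumerate(segments):
            if seg.start_t - tolerance <= ts <= seg.end_t + tolerance:
                dist = abs(seg.peak_t - ts)
                if dist < best_dist:  # strict: ties keep the earlier segment
                    best, best_dist = i, dist
        if best is None:
            missed += 1
        else:
            labels[best] = True
    return labels, missed


@dataclass
class RocResult:
    """ROC sweep: thresholds, operating points, and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_points_frame(self):
        import pandas as pd

        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores: np.ndarray | Sequence[float], labels: np.ndarray | Sequence[bool]) -> RocResult:
    """ROC curve and AUC from per-segment scores and valid/invalid labels.

    All distinct score values are swept (equal scores collapse into one
    operating point); TPR = TP/(TP+FN), FPR = FP/(FP+TN); AUC by the
    trapezoidal rule, which equals the Mann-Whitney concordance
    U / (n_pos * n_neg) with ties averaged.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise SingleClassError("ROC requires at least one positive and one negative")
    fpr, tpr, thr = _roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class CrossvalResult:
    """Per-method cross-validated AUC, Table-style ``mean +/- std``."""

    auc_mean: float
    auc_std: float
    fold_aucs: list[float]
    method: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "folds": self.fold_aucs,
        }

    def __str__(self) -> str:
        return f"{self.method}: AUC {self.auc_mean:.3f} +/- {self.auc_std:.3f}"


def _fold_scores(
    train_segs: list[Segment],
    train_labels: np.ndarray,
    val_segs: list[Segment],
    method: str,
    feature_kind: str,
    reference_xy: tuple[float, float],
    seed: int,
    confidence: float,
) -> np.ndarray:
    valid_train = [s for s, lab in zip(train_segs, train_labels) if lab]
    if len(valid_train) < 3:
        raise InsufficientPositivesError(
            f"fold has {len(valid_train)} valid training segments; need >= 3"
        )
    if method == "threshold":
        # under heavy involuntary motion some "valid" segments extend to the
        # wrong side of the reference; calibrate on the dominant direction
        extrema = np.array(
            [s.x[np.argmax(np.abs(s.x - reference_xy[0]))] - reference_xy[0] for s in valid_train]
        )
        majority = 1.0 if np.sum(extrema > 0) >= np.sum(extrema < 0) else -1.0
        keep = [s for s, e in zip(valid_train, extrema) if e * majority > 0]
        model = calibrate_threshold(keep, x_h0=reference_xy[0])
        return np.array([threshold_score(s, model) for s in val_segs])
    if method == "hmm":
        clf, _ = train_hmm_classifier(
            valid_train,
            feature_kind=feature_kind,
            reference_xy=reference_xy,
            seed=seed,
            confidence=confidence,
        )
        return np.array([clf.score(s) for s in val_segs])
    raise ValueError(f"unknown method {method!r}")


def crossval_auc(
    segments: Sequence[Segment],
    labels: np.ndarray | Sequence[bool],
    method: str = "hmm",
    feature_kind: str = "PV",
    k: int = 3,
    seed: int = 0,
    reference_xy: tuple[float, float] = (0.0, 0.0),
    confidence: float = 0.95,
) -> CrossvalResult:
    """Stratified k-fold cross-validated AUC for one classifier.

    Per fold the classifier is trained on the training split's valid
    segments (HMM + psi null, or threshold calibration) and scores the
    validation split; the per-fold AUCs are summarized as mean and sample
    standard deviation.
    """
    segments = list(segments)
    labels = np.asarray(labels, bool)
    if labels.sum() < k:
        raise InsufficientPositivesError(
            f"{int(labels.sum())} valid segments cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(segments)), labels.astype(int))):
        val_labels = labels[va]
        if val_labels.all() or not val_labels.any():
            raise InsufficientPositivesError(f"fold {fold} validation split is single-class")
        scores = _fold_scores(
            [segments[i] for i in tr],
            labels[tr],
            [segments[i] for i in va],
            method,
            feature_kind,
            reference_xy,
            seed=(seed * 97 + fold) % (2**31 - 1),
            confidence=confidence,
        )
        fold_aucs.append(roc_auc(scores, val_labels).auc)
    name = method if method == "threshold" else f"hmm-{feature_kind.lower()}"
    return CrossvalResult(
        auc_mean=float(np.mean(fold_aucs)),
        auc_std=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        fold_aucs=[float(a) for a in fold_aucs],
        method=name,
    )


def write_report(results: Sequence[CrossvalResult], path: str | Path) -> None:
    """JSON report: per-method ``{auc_mean, auc_std, folds}``."""
    payload = {r.method: r.to_dict() for r in results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
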