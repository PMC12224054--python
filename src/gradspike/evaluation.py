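"""Scoring of sorting and detection against ground truth.

Sorting accuracy is the fraction of spikes whose predicted cluster maps to
their true unit under the optimal one-to-one cluster assignment (Hungarian
on the confusion matrix); it is reported overall and split by overlap
flags when present.  Detection is scored by greedy one-to-one matching of
event times within a tolerance, yielding precision/recall/F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import GroundTruth
from .clustering_selection import ClusterLabels, SortResult


@dataclass
class MatchReport:
    """Cluster-to-unit assignment and the accuracies it implies (percent)."""

    assignment: Dict[int, int]  # predicted cluster -> true unit
    accuracy: float
    accuracy_nonoverlap: Optional[float]
    accuracy_overlap: Optional[float]
    confusion: np.ndarray
    pred_values: np.ndarray
    true_values: np.ndarray


@dataclass
class DetectionReport:
    """Counts and rates from time-matched detection scoring."""

    tp: int
    fp: int
    fn: int
    tolerance: float
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        denom = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / denom if denom else 0.0


def confusion_matrix(pred: np.ndarray, true: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts of (predicted cluster, true unit) co-occurrences."""
    pred_vals, pred_idx = np.unique(pred, return_inverse=True)
    true_vals, true_idx = np.unique(true, return_inverse=True)
    C = np.zeros((len(pred_vals), len(true_vals)), dtype=int)
    np.add.at(C, (pred_idx, true_idx), 1)
    return C, pred_vals, true_vals


def match_labels(pred, truth, overlap_flags: Optional[np.ndarray] = None
                 ) -> MatchReport:
    """Score predicted labels against true unit ids.

    The one-to-one predicted-to-true assignment maximizing the total number
    of matched spikes is found on the confusion matrix; spikes in unmatched
    predicted clusters count as errors.  Accuracy is a percentage of all
    spikes, additionally split by ``overlap_flags`` when available.
    """
    pred_labels = pred.labels if isinstance(pred, ClusterLabels) else np.asarray(pred)
    if isinstance(truth, GroundTruth):
        true_labels = truth.unit_ids
        if overlap_flags is None:
            overlap_flags = truth.overlap_flags
    else:
        true_labels = np.asarray(truth)
    if len(pred_labels) != len(true_labels):
        raise ValueError("predicted and true labels must have equal length")

    C, pred_vals, true_vals = confusion_matrix(pred_labels, true_labels)
    rows, cols = linear_sum_assignment(C, maximize=True)
    assignment = {int(pred_vals[r]): int(true_vals[c]) for r, c in zip(rows, cols)}

    mapped = np.full(len(pred_labels), np.nan, dtype=object)
    for pv, tv in assignment.items():
        mapped[pred_labels == pv] = tv
    correct = np.array([m == t for m, t in zip(mapped, true_labels)])

    def pct(mask: np.ndarray) -> Optional[float]:
        return 100.0 * correct[mask].mean() if mask.any() else None

    acc = 100.0 * correct.mean() if len(correct) else 0.0
    acc_no, acc_ov = None, None
    if overlap_flags is not None:
        flags = np.asarray(overlap_flags, dtype=bool)
        acc_no = pct(~flags)
        acc_ov = pct(flags)
    return MatchReport(assignment, acc, acc_no, acc_ov, C, pred_vals, true_vals)


def detection_metrics(detected_times: np.ndarray, true_times: np.ndarray,
                      tolerance: float = 1e-3) -> DetectionReport:
    """Greedy one-to-one time matching within ``tolerance`` seconds.

    Both lists must be sorted.  Each true spike absorbs at most one
    detection; unmatched detections are false positives, unmatched true
    spikes false negatives.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    det = np.asarray(detected_times, dtype=float)
    tru = np.asarray(true_times, dtype=float)
    if np.any(np.diff(det) < 0) or np.any(np.diff(tru) < 0):
        raise ValueError("time lists must be sorted")
    tp = 0
    i = j = 0
    while i < len(det) and j < len(tru):
        dt = det[i] - tru[j]
        if abs(dt) <= tolerance:
            tp += 1
            i += 1
            j += 1
        elif dt < -tolerance:
            i += 1
        else:
            j += 1
    return DetectionReport(tp, len(det) - tp, len(tru) - tp, tolerance)


def match_spike_trains(detected_times: np.ndarray, true_times: np.ndarray,
                       tolerance: float = 1e-3
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one pairing; returns matched index arrays (det, true)."""
    det = np.asarray(detected_times, dtype=float)
    tru = np.asarray(true_times, dtype=float)
    det_idx, tru_idx = [], []
    i = j = 0
    while i < len(det) and j < len(tru):
        dt = det[i] - tru[j]
        if abs(dt) <= tolerance:
            det_idx.append(i)
            tru_idx.append(j)
            i += 1
            j += 1
        elif dt < -tolerance:
            i += 1
        else:
            j += 1
    return np.array(det_idx, dtype=int), np.array(tru_idx, dtype=int)


def unit_detection_rate(pred, truth: GroundTruth,
                        min_share: float = 0.5) -> float:
    """Percentage of true units recovered as a distinct cluster.

    A unit counts as detected when the cluster assigned to it (one-to-one
    optimal assignment on the confusion matrix) captures at least
    ``min_share`` of its spikes — a unit wholly absorbed into a cluster
    already claimed by another unit is missed.
    """
    pred_labels = pred.labels.labels if isinstance(pred, SortResult) else (
        pred.labels if isinstance(pred, ClusterLabels) else np.asarray(pred))
    C, _, true_vals = confusion_matrix(pred_labels, truth.unit_ids)
    rows, cols = linear_sum_assignment(C, maximize=True)
    unit_sizes = C.sum(axis=0)
    detected = np.zeros(len(true_vals), dtype=bool)
    for r, c in zip(rows, cols):
        if unit_sizes[c] > 0 and C[r, c] >= min_share * unit_sizes[c]:
            detected[c] = True
    return 100.0 * detected.mean()


def per_unit_accuracy(pred_labels: np.ndarray, true_labels: np.ndarray,
                      n_missed: Dict[object, int] | None = None
                      ) -> Dict[object, float]:
    """Agreement score per true unit: ``tp / (tp + fp + fn)``, in percent.

    Each true unit is paired with a predicted cluster by optimal assignment
    on the confusion matrix; ``tp`` are the unit's spikes in that cluster,
    ``fn`` its spikes elsewhere (plus optional undetected counts passed via
    ``n_missed``), ``fp`` the cluster's remaining spikes.  Units with no
    assigned cluster score 0.
    """
    C, pred_vals, true_vals = confusion_matrix(pred_labels, true_labels)
    rows, cols = linear_sum_assignment(C, maximize=True)
    col_of = {c: r for r, c in zip(rows, cols)}
    out: Dict[object, float] = {}
    for t, tv in enumerate(true_vals):
        n_true = C[:, t].sum() + (n_missed.get(tv, 0) if n_missed else 0)
        if t not in col_of:
            out[tv] = 0.0
            continue
        r = col_of[t]
        tp = C[r, t]
        fp = C[r, :].sum() - tp
        fn = n_true - tp
        out[tv] = 100.0 * tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    if n_missed:
        for tv, miss in n_missed.items():
            if tv not in out and miss > 0:
                out[tv] = 0.0
    return out
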