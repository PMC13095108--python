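"""Evaluation metrics: Hand–Till multiclass AUC, precision/recall, confusion.

The Hand–Till construction extends binary AUC to C classes by averaging,
over every unordered class pair {i, j}, the symmetrized pairwise AUC
A_hat(i, j) = [A(c_i|c_j) + A(c_j|c_i)] / 2, where A(c_i|c_j) ranks the
class-i probability column over the samples of classes i and j. Ties are
handled with midranks, so uninformative constant scores give 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["ScoredSet", "EvalReport", "pairwise_auc", "hand_till_mauc", "confusion_and_prf"]


@dataclass
class ScoredSet:
    """Per-sample class-probability rows plus true labels."""

    probs: np.ndarray  # (n, C), rows on the simplex
    labels: np.ndarray  # (n,), int class indices

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.labels.shape[0]:
            raise ValueError("probs must be (n, C) aligned with labels (n,)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1 within 1e-6")


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) and headline metrics."""

    confusion: np.ndarray
    mauc: float
    precision_macro: float
    recall_macro: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    class_names: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "confusion": self.confusion.tolist(),
            "mauc": float(self.mauc),
            "precision_macro": float(self.precision_macro),
            "recall_macro": float(self.recall_macro),
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "class_names": list(self.class_names),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def format_table(self) -> str:
        names = self.class_names or [str(i) for i in range(self.confusion.shape[0])]
        width = max(7, max(len(n) for n in names) + 1)
        lines = ["confusion (rows=true, cols=pred):"]
        lines.append(" " * width + "".join(f"{n:>{width}}" for n in names))
        for name, row in zip(names, self.confusion):
            lines.append(f"{name:>{width}}" + "".join(f"{int(v):>{width}}" for v in row))
        lines.append(f"mAUC            {self.mauc:.4f}")
        lines.append(f"precision_macro {self.precision_macro:.4f}")
        lines.append(f"recall_macro    {self.recall_macro:.4f}")
        return "\n".join(lines)


def pairwise_auc(scores_i: Sequence[float], scores_j: Sequence[float]) -> float:
    """A(c_i|c_j): rank-sum AUC of class-i scores against class-j scores.

    ``scores_i`` are class-i samples' scores for class i; ``scores_j`` are
    class-j samples' scores for class i. Midranks handle ties, so the
    result is the probability a random class-i sample outranks a random
    class-j sample, ties counting one half.
    """
    si = np.asarray(scores_i, dtype=np.float64)
    sj = np.asarray(scores_j, dtype=np.float64)
    ni, nj = si.size, sj.size
    if ni == 0 or nj == 0:
        raise ValueError("pairwise AUC undefined for an empty class group")
    ranks = rankdata(np.concatenate([si, sj]), method="average")
    s_ij = ranks[:ni].sum()
    return float((s_ij - ni * (ni + 1) / 2.0) / (ni * nj))


def hand_till_mauc(s: ScoredSet) -> float:
    """Mean of symmetrized pairwise AUCs over all class pairs present."""
    present = np.unique(s.labels)
    if present.size < 2:
        raise ValueError("Hand-Till mAUC needs at least 2 classes present")
    n_classes = s.probs.shape[1]
    absent = [c for c in range(n_classes) if c not in set(present.tolist())]
    if absent:
        warnings.warn(f"classes absent from labels, skipped in mAUC: {absent}")
    vals = []
    for a, i in enumerate(present):
        for j in present[a + 1:]:
            mask_i = s.labels == i
            mask_j = s.labels == j
            a_ij = pairwise_auc(s.probs[mask_i, i], s.probs[mask_j, i])
            a_ji = pairwise_auc(s.probs[mask_j, j], s.probs[mask_i, j])
            vals.append(0.5 * (a_ij + a_ji))
    return float(np.mean(vals))


def confusion_and_prf(s: ScoredSet, class_names: Sequence[str] = ()) -> EvalReport:
    """Argmax predictions (ties -> lowest index), confusion matrix, macro P/R.

    Classes never predicted get precision 0 (with a warning); classes
    absent from the labels get recall 0 likewise. Macro averages run over
    classes present in the labels.
    """
    n_classes = s.probs.shape[1]
    pred = np.argmax(s.probs, axis=1)  # argmax breaks ties toward lowest index
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (s.labels, pred), 1)

    tp = np.diag(conf).astype(np.float64)
    pred_tot = conf.sum(axis=0).astype(np.float64)
    true_tot = conf.sum(axis=1).astype(np.float64)
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(tp, pred_tot, out=precision, where=pred_tot > 0)
        np.divide(tp, true_tot, out=recall, where=true_tot > 0)
    if np.any((pred_tot == 0) & (true_tot > 0)):
        warnings.warn("some classes were never predicted; their precision is 0")

    present = true_tot > 0
    try:
        mauc = hand_till_mauc(s)
    except ValueError:
        mauc = float("nan")
    return EvalReport(
        confusion=conf,
        mauc=mauc,
        precision_macro=float(precision[present].mean()),
        recall_macro=float(recall[present].mean()),
        per_class_precision=precision,
        per_class_recall=recall,
        class_names=list(class_names),
    )
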