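"""Classification metrics over score columns and parallel-performance metrics.

Network quality is judged per TF on the out-of-fold decision scores:
precision/recall/F1 at a stated threshold (default 0, the SVM decision
boundary), ranking AUC (Mann-Whitney, ties count 1/2) and AUPR (area
under the precision-recall curve by rectangular integration over
descending thresholds).  Averages are unweighted means over evaluated
TFs.

Parallel performance follows the classical definitions: speedup
S(j) = T(1)/T(j), efficiency E(j) = S(j)/j, redundancy R(j) = O(j)/O(1)
(operation counts), quality Q(j) = S(j) E(j) / R(j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import RegulationMatrix, ScoreMatrix

__all__ = [
    "PerfRecord",
    "EvalReport",
    "pr_f1",
    "auc",
    "aupr",
    "cv_report",
    "perf_metrics",
]


@dataclass
class PerfRecord:
    """Wall times and abstract operation counts for a sequential (T1, O1)
    and a j-worker (Tj, Oj) run of the same inference problem."""

    T1: float
    Tj: float
    j: int
    O1: float = 1.0
    Oj: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T1", "Tj", "j", "O1", "Oj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EvalReport:
    per_tf: pd.DataFrame
    threshold: float
    n_skipped: int = 0

    @property
    def averages(self) -> dict[str, float]:
        cols = [c for c in ("precision", "recall", "f1", "auc", "aupr") if c in self.per_tf]
        return {c: float(self.per_tf[c].mean()) for c in cols}

    def to_tsv(self, path) -> None:
        df = self.per_tf.copy()
        avg = {"tf": "AVERAGE", **self.averages}
        df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if not set(np.unique(labels)) <= {-1.0, 1.0}:
        raise ValueError("labels must be +-1")
    return labels


def pr_f1(scores, labels, threshold: float = 0.0) -> tuple[float, float, float]:
    """Precision, recall and F1 of the classifier (score >= threshold).

    Precision is reported as 1.0 (vacuously) when nothing is predicted
    positive, so F1 still reflects the zero recall.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if not (labels == 1).any():
        raise ValueError("recall undefined: no positive labels")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == -1)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if len(set(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (rectangular integration over
    descending unique score thresholds; equals average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if len(set(labels)) < 2:
        raise ValueError("AUPR undefined for single-class labels")
    return float(average_precision_score(labels, scores))


def cv_report(
    ds: ScoreMatrix,
    R: RegulationMatrix,
    threshold: float = 0.0,
    exclude_training_positives: bool = False,
) -> EvalReport:
    """Per-TF and averaged metrics of a score matrix against labels.

    Only TFs with status "ok" and >= 1 positive label (after the optional
    exclusion of known training positives, which requires R.known_mask)
    are evaluated; others are counted in ``n_skipped``.  Averages are
    unweighted means over evaluated TFs.
    """
    if ds.gene_ids != R.gene_ids:
        raise ValueError("score matrix and regulation matrix are not aligned")
    if exclude_training_positives and R.known_mask is None:
        raise ValueError("exclude_training_positives requires a known_mask")
    rows = []
    n_skipped = 0
    for j, tf in enumerate(R.tf_ids):
        if tf not in ds.tf_ids or ds.column_status.get(tf) != "ok":
            n_skipped += 1
            continue
        y = R.labels[:, j].astype(float)
        y[y == 0] = -1.0
        s = ds.column(tf)
        keep = ~np.isnan(s)
        if exclude_training_positives:
            keep &= ~(R.known_mask[:, j] & (R.labels[:, j] == 1))
        y, s = y[keep], s[keep]
        if not (y == 1).any() or not (y == -1).any():
            n_skipped += 1
            continue
        precision, recall, f1 = pr_f1(s, y, threshold)
        rows.append(
            {
                "tf": tf,
                "n_pos": int((y == 1).sum()),
                "n_neg": int((y == -1).sum()),
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "auc": auc(s, y),
                "aupr": aupr(s, y),
            }
        )
    if not rows:
        raise ValueError("no evaluable TF column")
    return EvalReport(pd.DataFrame(rows), threshold, n_skipped)


def perf_metrics(rec: PerfRecord) -> tuple[float, float, float, float]:
    """Speedup, efficiency, redundancy and quality of a parallel run."""
    S = rec.T1 / rec.Tj
    E = S / rec.j
    R = rec.Oj / rec.O1
    Q = S * E / R
    return S, E, R, Q
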