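"""Binary-classification metrics: Sen, Spe, Acc, MCC, ROC and AUC.

Point metrics are computed from the confusion matrix at a fixed score
threshold (default 0.5, score >= threshold predicts positive):

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

with MCC defined as 0 whenever a denominator factor vanishes.  AUC is the
Mann-Whitney probability that a random positive outscores a random negative
(ties counting one half), equal to trapezoidal ROC integration; ROC/AUC are
delegated to scikit-learn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(labels, scores, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix; score >= threshold predicts positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)))


def point_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sen, Spe, Acc, MCC) from confusion counts.

    Sen/Spe fall back to 0 when their class is absent; MCC falls back to 0
    when any denominator factor is zero (the standard convention for the
    otherwise-undefined ratio).
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("no counts")
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sen, spe, acc, mcc


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """AUC and the ROC curve as an array of (FPR, TPR) points."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report (point metrics at ``threshold`` plus AUC) for one model."""
    sen, spe, acc, mcc = point_metrics(confusion(labels, scores, threshold))
    auc, _ = roc_auc(labels, scores)
    return MetricsReport(sen=sen, spe=spe, acc=acc, mcc=mcc, auc=auc,
                         threshold=threshold)


def write_report(report: MetricsReport, json_path: str | Path,
                 tsv_path: str | Path | None = None,
                 row_name: str = "model") -> None:
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2))
    if tsv_path is not None:
        d = report.to_dict()
        keys = list(d)
        header = "name\t" + "\t".join(keys) + "\n"
        line = row_name + "\t" + "\t".join(f"{d[k]:.6g}" for k in keys) + "\n"
        p = Path(tsv_path)
        if p.exists():
            p.write_text(p.read_text() + line)
        else:
            p.write_text(header + line)


def write_roc(points: np.ndarray, path: str | Path) -> None:
    """ROC points as a 2-column (FPR, TPR) TSV."""
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")
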