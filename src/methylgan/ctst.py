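"""Classifier two-sample test (CTST) and GAN checkpoint selection.

The CTST asks whether synthetic features are distinguishable from real ones:
pool the two samples (real labeled 1, synthetic labeled 0) and score a
1-nearest-neighbour classifier under leave-one-out cross-validation.  An
accuracy near 1 means the sets are trivially separable; an accuracy near 0.5
means the generator has matched the real distribution (accuracy near 0 means
the synthetic points sit pathologically on top of the real ones).  The
checkpoint whose accuracy is closest to 0.5 is selected, ties going to the
earliest epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .gan import FeatureBatch, GanCheckpoint, generate_synthetic


@dataclass(frozen=True)
class CtstResult:
    """CTST accuracies per evaluated checkpoint epoch, plus the selection."""

    accuracies: dict[int, float]
    selected_epoch: int

    def save(self, path: str | Path, class_label: int | None = None) -> None:
        Path(path).write_text(json.dumps({
            "epochs": sorted(self.accuracies),
            "accuracies": {str(k): v for k, v in sorted(self.accuracies.items())},
            "selected_epoch": self.selected_epoch,
            "class": class_label}, indent=2))


def ctst_accuracy(real: np.ndarray, synthetic: np.ndarray) -> float:
    """Leave-one-out 1-NN accuracy at telling real rows from synthetic rows.

    Real rows are labeled 1 and synthetic rows 0; every pooled point is a
    test point whose prediction is the label of its nearest Euclidean
    neighbour (self excluded, distance ties broken by lowest row index).
    Exact O(n^2) computation.
    """
    real = np.atleast_2d(np.asarray(real, dtype=float))
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=float))
    if real.size == 0 or synthetic.size == 0:
        raise ValueError("both sets must be non-empty")
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError(f"dimensionality mismatch: {real.shape[1]} vs "
                         f"{synthetic.shape[1]}")
    pooled = np.vstack([real, synthetic])
    if len(pooled) < 2:
        raise ValueError("need at least 2 pooled points")
    labels = np.concatenate([np.ones(len(real)), np.zeros(len(synthetic))])
    dist = cdist(pooled, pooled)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.argmin(axis=1)  # argmin returns the lowest index on ties
    return float(np.mean(labels[nearest] == labels))


def select_checkpoint(evaluated: list[tuple[int, float]]) -> int:
    """Epoch whose CTST accuracy is closest to 0.5; ties -> earliest epoch."""
    if not evaluated:
        raise ValueError("no evaluated checkpoints")
    return min(sorted(evaluated), key=lambda ea: abs(ea[1] - 0.5))[0]


def evaluate_checkpoints(real: FeatureBatch, checkpoints: list[GanCheckpoint],
                         seed: int, n_synthetic: int | None = None
                         ) -> CtstResult:
    """Score every checkpoint against the real single-class features.

    For each checkpoint, ``n_synthetic`` rows (default: as many as there are
    real rows, giving a balanced pooled test) are generated and the CTST
    accuracy computed; the accuracy is recorded on the checkpoint and the
    closest-to-0.5 epoch selected.
    """
    if len(np.unique(real.labels)) != 1:
        raise ValueError("CTST is evaluated per class; mixed labels passed")
    n = n_synthetic if n_synthetic is not None else real.n
    label = int(real.labels[0])
    accs: dict[int, float] = {}
    for ck in checkpoints:
        synth = generate_synthetic(ck, n, label, real.layer_shape,
                                   seed=seed + ck.epoch)
        acc = ctst_accuracy(real.values, synth.values)
        ck.ctst_accuracy = acc
        accs[ck.epoch] = acc
    selected = select_checkpoint(list(accs.items()))
    return CtstResult(accuracies=accs, selected_epoch=selected)
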