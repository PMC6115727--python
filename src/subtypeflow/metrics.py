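"""Confusion matrices and imbalance-aware classification scores.

Weight accuracy (wAcc) is the unweighted mean of per-class recalls,

    wAcc = (1/c) * sum_i n_ii / (n_i1 + ... + n_ic),

which gives every class the same say regardless of its size; plain accuracy
is trace / total and can be dominated by a majority class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """Counts with entry (i, j) = samples of true class i predicted as j."""

    counts: np.ndarray
    class_ids: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        c = len(self.class_ids)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be c x c for c = len(class_ids)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred, class_ids=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if class_ids is None:
            class_ids = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(class_ids)}
        counts = np.zeros((len(class_ids), len(class_ids)))
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_ids=list(class_ids))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if list(other.class_ids) != list(self.class_ids):
            raise ValueError("class_ids mismatch")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_ids))


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    row = cm.counts.sum(axis=1)
    if np.any(row == 0):
        empty = [cm.class_ids[i] for i in np.nonzero(row == 0)[0]]
        raise ValueError(f"empty class rows: {empty}")
    return np.diag(cm.counts) / row


def weight_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls; robust to class imbalance."""
    return float(per_class_recall(cm).mean())


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of all samples classified correctly (trace / total)."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def cross_tabulate(labels_a: dict, labels_b: dict) -> pd.DataFrame:
    """Generic cross-tabulation of two label assignments over the same ids
    (rows: labels_a values, columns: labels_b values)."""
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("no shared ids between the two label sets")
    a = [labels_a[i] for i in common]
    b = [labels_b[i] for i in common]
    return pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
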