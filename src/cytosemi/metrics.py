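"""Confusion matrices, per-class precision and macro-precision.

Macro-precision (macro-P) is the unweighted mean over classes of
``P_i = TP_i / (TP_i + FP_i)`` where, with rows as true class and columns as
predicted class, ``TP_i`` is the diagonal entry and ``FP_i`` the rest of
column i.  A class never predicted has an undefined ratio; it is scored 0
(conservative) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "confusion_matrix",
    "precision_per_class",
    "macro_precision",
    "row_mean_difference",
]


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """n x n count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def precision_per_class(cm) -> np.ndarray:
    """Per-class precision TP_i / (TP_i + FP_i) from a confusion matrix."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    col_sums = cm.sum(axis=0).astype(float)
    tp = np.diag(cm).astype(float)
    out = np.zeros(cm.shape[0])
    for i in range(cm.shape[0]):
        if col_sums[i] == 0:
            warnings.warn(f"class {i} was never predicted; precision set to 0",
                          stacklevel=2)
        else:
            out[i] = tp[i] / col_sums[i]
    return out


def macro_precision(cm) -> float:
    """Unweighted mean of per-class precision."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(precision_per_class(cm).mean())


def row_mean_difference(row_a, row_b) -> float:
    """Difference of row means, in the units of the inputs.

    Used to aggregate published accuracy tables, which print percentages —
    the result is then in percentage points.
    """
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    return float(a.mean() - b.mean())
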