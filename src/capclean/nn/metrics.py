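"""Binary classification metrics for patch evaluation.

The dirty class (intestinal content) is the positive class.  Accuracy,
sensitivity and specificity are reported as percentages; the Matthews
correlation coefficient (MCC) lies in [-1, 1].  Degenerate confusion matrices
(a zero denominator in any formula) set the corresponding ``*_defined`` flag
to False and the metric to NaN, except MCC which is 0 by convention when its
denominator vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ClassificationMetrics", "metrics_from_confusion", "evaluate"]


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float  # percent
    sensitivity: float  # percent, NaN if undefined
    specificity: float  # percent, NaN if undefined
    mcc: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True
    mcc_defined: bool = True


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> ClassificationMetrics:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (tp + tn) / total
    sens_def = (tp + fn) > 0
    spec_def = (tn + fp) > 0
    sensitivity = 100.0 * tp / (tp + fn) if sens_def else float("nan")
    specificity = 100.0 * tn / (tn + fp) if spec_def else float("nan")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc_def = denom > 0
    mcc = (tp * tn - fp * fn) / denom if mcc_def else 0.0
    return ClassificationMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity, mcc=mcc,
        sensitivity_defined=sens_def, specificity_defined=spec_def, mcc_defined=mcc_def,
    )


def evaluate(net, x: np.ndarray, y: np.ndarray) -> ClassificationMetrics:
    """Evaluate a trained network; labels 0 = clean, 1 = dirty (positive).

    Predictions threshold the dirty probability at 0.5.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    probs = net.predict_proba(x)
    pred = (probs[:, 1] >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return metrics_from_confusion(tp, tn, fp, fn)
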