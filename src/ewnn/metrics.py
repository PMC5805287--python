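"""Confusion-matrix statistics and per-patient aggregation.

Convention note: in the biomedical reporting convention adopted throughout
this package the *positive class is the control (non-diseased) class*, i.e.
a true positive is a control sample classified as control and a false
negative is a diseased sample classified as control's complement.  The
``positive_class`` argument makes the conventional (diseased-positive)
usage available as well, but every built-in report uses control-positive.

Sensitivity and specificity are undefined when their denominator is zero
(e.g. a test fold containing no control samples); such values are carried
as NaN and printed as "-".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Flag value for a metric whose denominator is zero.
NOT_COMPUTABLE = float("nan")


def is_computable(x: float) -> bool:
    return not math.isnan(x)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; ``tp + tn + fp + fn`` equals the sample count."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(truth, pred, positive_class: int = 0) -> ConfusionCounts:
    """Tally a confusion matrix with an explicit positive class.

    The default ``positive_class=0`` is the control-positive convention
    described in the module docstring.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1 or len(truth) < 1:
        raise ValueError("truth and pred must be equal-length nonempty 1-D arrays")
    t_pos = truth == positive_class
    p_pos = pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (P + N)."""
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when no positive-class samples were scored."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else NOT_COMPUTABLE


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when no negative-class samples were scored."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else NOT_COMPUTABLE


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, defined as 0
    when any factor of the denominator vanishes (standard convention).
    """
    w1 = c.tp * c.tn - c.fp * c.fn
    w2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if w2 == 0:
        return 0.0
    return w1 / math.sqrt(w2)


def classification_metrics(truth, pred, positive_class: int = 0) -> dict:
    """All scalar metrics for one truth/prediction pair, as fractions."""
    c = confusion(truth, pred, positive_class)
    return {
        "accuracy": accuracy(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "mcc": mcc(c),
        "confusion": c,
    }


def aggregate_patients(record_preds, patient_ids):
    """Collapse record-level predictions to one label per individual.

    An individual is labelled diseased (1) iff *strictly more than half* of
    their records are predicted diseased; an exact tie goes to control.

    Returns ``(ids, labels)`` with ids in order of first appearance.
    """
    record_preds = np.asarray(record_preds)
    patient_ids = np.asarray(patient_ids)
    if record_preds.shape != patient_ids.shape:
        raise ValueError("record_preds and patient_ids must have equal length")
    order: dict = {}
    counts: dict = {}
    for pid, p in zip(patient_ids, record_preds):
        key = pid.item() if hasattr(pid, "item") else pid
        if key not in order:
            order[key] = len(order)
            counts[key] = [0, 0]
        counts[key][int(p)] += 1
    ids = list(order)
    labels = np.array([1 if counts[k][1] * 2 > sum(counts[k]) else 0 for k in ids])
    return np.array(ids), labels


def format_percent(x: float, decimals: int = 1) -> str:
    """Fraction -> percentage string with ``decimals`` places; NaN -> '-'."""
    if not is_computable(x):
        return "-"
    return f"{100.0 * x:.{decimals}f}"


def metrics_row(name: str, te_acc: float, ete_acc: float, sens: float,
                spec: float, mcc_value: float) -> str:
    """One tab-separated report row, percentages to 1 decimal place."""
    cells = [name] + [format_percent(v) for v in (te_acc, ete_acc, sens, spec, mcc_value)]
    return "\t".join(cells)


METRICS_HEADER = "\t".join(["dataset", "Te_acc", "ETe_acc", "Sens", "Spec", "MCC"])
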