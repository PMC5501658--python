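"""Confusion matrices, derived classification statistics, ROC curves.

The pathogenic class is the positive class throughout.  Statistics follow
the standard contingency definitions: specificity TN/(FP+TN), sensitivity
TP/(TP+FN), accuracy (TP+TN)/N, precision TP/(TP+FP), FDR FP/(TP+FP) (the
complement of precision, not a multiple-testing quantity), the Matthews
correlation coefficient, and the misclassification rate MCR =
100*(FP+FN)/N.  All are computed over predicted variants only: rows where a
tool made no call are excluded from the counts and N reflects that.

Zero denominators yield NaN (MCC's zero denominator yields 0 by the common
convention) — never an exception.  Display rounding is half-up to 2
decimals; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import math
import numpy as np
import pandas as pd

from .exceptions import ValidationError

NO_CALL = None  #: entries compared as "no prediction" and excluded from counts


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (Python's round is banker's)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with pathogenic as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.n_predicted < 1:
            raise ValidationError("confusion matrix must count at least one prediction")

    @property
    def n_predicted(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    specificity: float
    sensitivity: float
    accuracy: float
    precision: float
    fdr: float
    mcc: float
    mcr: float
    n_predicted: int

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        d = {k: (v if k == "n_predicted" else round_half_up(v, ndigits))
             for k, v in asdict(self).items()}
        return MetricsReport(**d)

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def _is_no_call(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


def confusion(true_labels, calls) -> ConfusionMatrix:
    """Count TP/TN/FP/FN over jointly present entries.

    Labels/calls may be {pathogenic, neutral}, {P, N} or +/-1 (-1 =
    pathogenic); call entries of None/NaN count as "no prediction" and are
    excluded.
    """
    t = list(true_labels)
    c = list(calls)
    if len(t) != len(c):
        raise ValidationError("true labels and calls have different lengths")

    def as_positive(v):
        if v in ("pathogenic", "P", -1, -1.0):
            return True
        if v in ("neutral", "N", 1, 1.0):
            return False
        raise ValidationError(f"unrecognized label/call {v!r}")

    tp = tn = fp = fn = 0
    for yt, yc in zip(t, c):
        if _is_no_call(yc):
            continue
        truth, call = as_positive(yt), as_positive(yc)
        if truth and call:
            tp += 1
        elif truth and not call:
            fn += 1
        elif not truth and call:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num, den) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The seven derived statistics of a confusion matrix (see module doc)."""
    n = cm.n_predicted
    mcc_den = math.sqrt(float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    mcc = ((cm.tp * cm.tn - cm.fp * cm.fn) / mcc_den) if mcc_den > 0 else 0.0
    return MetricsReport(
        specificity=_ratio(cm.tn, cm.fp + cm.tn),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        accuracy=(cm.tp + cm.tn) / n,
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        fdr=_ratio(cm.fp, cm.tp + cm.fp),
        mcc=mcc,
        mcr=100.0 * (cm.fp + cm.fn) / n,
        n_predicted=n,
    )


def roc_curve(probabilities, true_labels):
    """Threshold sweep over distinct probabilities -> (fpr, tpr, auc).

    The curve starts at (0,0) and ends at (1,1); AUC is the trapezoid-rule
    area, which equals the Mann–Whitney concordant-pair fraction with ties
    counted 1/2.  Raises on single-class truth (AUC undefined).
    """
    p = np.asarray(probabilities, dtype=float)
    if not np.isfinite(p).all():
        raise ValidationError("probabilities must be finite")
    pos = np.array([v in ("pathogenic", "P", -1, -1.0) for v in true_labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC/AUC undefined with single-class truth")
    order = np.argsort(-p, kind="mergesort")
    p_sorted, pos_sorted = p[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    distinct = np.nonzero(np.diff(p_sorted))[0]
    idx = np.concatenate([distinct, [p.size - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / n_pos])
    fpr = np.concatenate([[0.0], fps[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def pairwise_concordance(calls_a, calls_b) -> float:
    """Fraction of jointly predicted positions on which two tools agree.

    Positions where either tool made no call shrink the denominator only;
    zero jointly-called positions yield NaN.
    """
    a, b = list(calls_a), list(calls_b)
    if len(a) != len(b):
        raise ValidationError("call vectors have different lengths")
    joint = agree = 0
    for va, vb in zip(a, b):
        if _is_no_call(va) or _is_no_call(vb):
            continue
        joint += 1
        agree += int(va == vb)
    return agree / joint if joint else float("nan")


TABLE_COLUMNS = ["tp", "tn", "fp", "fn", "specificity", "sensitivity",
                 "accuracy", "precision", "fdr", "mcc", "mcr", "n_predicted"]


def metrics_table(named_confusions) -> pd.DataFrame:
    """Evaluation report: one row per classifier, Table-style column order."""
    rows = []
    for name, cm in named_confusions:
        rep = compute_metrics(cm).rounded()
        rows.append({"classifier": name, "tp": cm.tp, "tn": cm.tn,
                     "fp": cm.fp, "fn": cm.fn, **asdict(rep)})
    return pd.DataFrame(rows, columns=["classifier"] + TABLE_COLUMNS)
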