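"""Per-residue classification metrics and threshold-sweep curves.

Terminology note: in this problem area "specificity" conventionally denotes
TP/(TP+FP) — the probability that a predicted interface residue is truly
interfacial, i.e. what the wider literature calls precision.  The metric set
reports it under both names.  A predictor that makes no positive predictions
would trivially achieve a perfect such specificity; degenerate denominators
therefore yield 0 together with an explicit flag, never 1.

ROC/PR curves and AUC come from a descending-score threshold sweep; the AUC
equals the Mann–Whitney probability that a positive outranks a negative,
with ties counted one half.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np


class MissingPolicy(str, enum.Enum):
    """How MISSING (NaN) predictions are counted."""

    EXCLUDE = "exclude"
    NEGATIVE = "count-as-negative"


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


def confusion(
    predictions,
    labels,
    missing_policy: MissingPolicy | str = MissingPolicy.EXCLUDE,
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over residues with defined predictions.

    ``predictions`` may be a float array with NaN for MISSING calls (the
    homology predictor leaves unaligned residues unpredicted); the policy
    either excludes those residues or counts them as negative calls.
    """
    missing_policy = MissingPolicy(missing_policy)
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have equal length")
    nan = np.isnan(pred)
    if missing_policy is MissingPolicy.EXCLUDE:
        pred, lab = pred[~nan], lab[~nan]
    else:
        pred = np.where(nan, 0.0, pred)
    p = pred.astype(int)
    return ConfusionCounts(
        TP=int(np.sum((p == 1) & (lab == 1))),
        FP=int(np.sum((p == 1) & (lab == 0))),
        TN=int(np.sum((p == 0) & (lab == 0))),
        FN=int(np.sum((p == 0) & (lab == 1))),
    )


@dataclass
class MetricSet:
    """Threshold metrics; ``degenerate`` lists metrics whose denominator was
    zero (reported as 0, never as a trivial 1)."""

    specificity_precision: float
    sensitivity_recall: float
    f_measure: float
    mcc: float
    degenerate: set = field(default_factory=set)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Precision-style specificity, recall, F-measure and MCC from counts."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    degenerate: set[str] = set()

    if c.TP + c.FP == 0:
        spec = 0.0
        degenerate.add("specificity_precision")
    else:
        spec = c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        sens = 0.0
        degenerate.add("sensitivity_recall")
    else:
        sens = c.TP / (c.TP + c.FN)
    if spec + sens == 0:
        f = 0.0
        degenerate.add("f_measure")
    else:
        f = 2 * spec * sens / (spec + sens)
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        mcc = 0.0
        degenerate.add("mcc")
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricSet(spec, sens, f, mcc, degenerate)


@dataclass
class CurveResult:
    """ROC and PR curves from one descending-score threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    auc_roc: float


def curves(scores, labels) -> CurveResult:
    """ROC/PR curves and AUC.

    Raises ``ValueError`` when the labels contain a single class.  NaN scores
    (MISSING predictions) are excluded from the sweep.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("curves need both classes present")
    fpr, tpr, roc_thr = roc_curve(y, s)
    prec, rec, pr_thr = precision_recall_curve(y, s)
    return CurveResult(fpr, tpr, roc_thr, prec, rec, pr_thr, auc_mann_whitney(s, y))


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability a positive outranks a negative (ties → ½),
    computed from rank sums."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def per_chain_macro(per_chain_counts: dict[str, ConfusionCounts]) -> MetricSet:
    """Macro average of the threshold metrics over chains (the alternative to
    the default residue-pooled aggregation)."""
    if not per_chain_counts:
        raise ValueError("no chains to average")
    sets = [metrics(c) for c in per_chain_counts.values()]
    degenerate = set().union(*(m.degenerate for m in sets))
    return MetricSet(
        float(np.mean([m.specificity_precision for m in sets])),
        float(np.mean([m.sensitivity_recall for m in sets])),
        float(np.mean([m.f_measure for m in sets])),
        float(np.mean([m.mcc for m in sets])),
        degenerate,
    )


def write_metrics_report(results: dict[str, MetricSet], path) -> None:
    """TSV metric report, one row per method."""
    with open(path, "w") as fh:
        fh.write("method\tspecificity_precision\tsensitivity_recall\tf_measure\tmcc\tdegenerate\n")
        for name, m in results.items():
            fh.write(
                f"{name}\t{m.specificity_precision:.4f}\t{m.sensitivity_recall:.4f}\t"
                f"{m.f_measure:.4f}\t{m.mcc:.4f}\t"
                f"{','.join(sorted(m.degenerate)) if m.degenerate else '-'}\n"
            )
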