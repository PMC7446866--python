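"""Classification performance metrics for a rare-outcome validation sample.

Provides the confusion-matrix summary at a probability threshold, the derived
metric set (sensitivity, specificity, balanced accuracy, PPV, NPV, lift over
prevalence, and the reciprocal of PPV = false positives per true positive),
and a rank-based (Mann-Whitney) AUC with midrank tie handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionSummary",
    "PerformanceReport",
    "confusion_at_threshold",
    "compute_auc",
    "compute_performance",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts at a fixed threshold; prediction is positive when p >= threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceReport:
    """Validation-sample performance metrics.

    Metrics whose denominator is zero are ``None`` (explicitly undefined,
    never silently 0). ``lift`` is PPV over outcome prevalence;
    ``flagged_reciprocal_ppv`` is 1/PPV, the number of flagged persons per
    true positive.
    """

    auc: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    lift: Optional[float]
    flagged_reciprocal_ppv: Optional[float]
    confusion: Optional[ConfusionSummary] = None
    prevalence: Optional[float] = None

    def as_percent_table(self, decimals: int = 1) -> dict:
        """Report-shaped dict: proportions as percentages to ``decimals``."""

        def pct(x):
            return None if x is None else round(100.0 * x, decimals)

        return {
            "auc": None if self.auc is None else round(self.auc, 2),
            "balanced_accuracy": pct(self.balanced_accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv),
            "npv": pct(self.npv),
            "lift": None if self.lift is None else round(self.lift, 1),
            "false_positives_per_true_positive": None
            if self.flagged_reciprocal_ppv is None
            else round(self.flagged_reciprocal_ppv, 1),
        }

    def summary(self) -> str:
        lines = ["Model performance", "-" * 42]
        for k, v in self.as_percent_table().items():
            lines.append(f"{k:<38}{'NA' if v is None else v}")
        return "\n".join(lines)


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionSummary:
    """Confusion counts with the inclusive rule: predicted positive iff p >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size == 0:
        raise ValueError("cannot compute a confusion matrix on empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, threshold=float(threshold))


def compute_auc(scores, labels) -> float:
    """Rank-based AUC: P(score of a random positive > random negative), ties 1/2.

    Computed from midranks, which is exactly the Mann-Whitney U statistic
    normalised by n1*n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def compute_performance(
    conf: ConfusionSummary,
    auc: Optional[float] = None,
    prevalence: Optional[float] = None,
) -> PerformanceReport:
    """Derive the full metric set from a confusion summary.

    ``prevalence`` (outcome prevalence in the evaluated sample) is needed for
    the lift; when omitted it is taken from the confusion counts themselves.
    """
    if conf.n == 0:
        raise ValueError("empty confusion summary")
    sens = _safe_div(conf.tp, conf.tp + conf.fn)
    spec = _safe_div(conf.tn, conf.tn + conf.fp)
    ba = None if sens is None or spec is None else (sens + spec) / 2.0
    ppv = _safe_div(conf.tp, conf.tp + conf.fp)
    npv = _safe_div(conf.tn, conf.tn + conf.fn)
    if prevalence is None:
        prevalence = (conf.tp + conf.fn) / conf.n
    lift = None if ppv is None or prevalence == 0 else ppv / prevalence
    recip = None if ppv is None or ppv == 0 else 1.0 / ppv
    if ba is not None:
        assert math.isclose(ba, (sens + spec) / 2.0)
    return PerformanceReport(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        ppv=ppv,
        npv=npv,
        lift=lift,
        flagged_reciprocal_ppv=recip,
        confusion=conf,
        prevalence=prevalence,
    )
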