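"""ROC/AUC evaluation, DeLong confidence intervals and confusion matrices.

AUC uses the Mann-Whitney formulation (ties count one half); the default
confidence interval is DeLong's fast variance estimator with a normal
interval clipped to [0, 1]; a seeded bootstrap percentile interval is
available as an alternative. Confusion-matrix rates are reported as
percentages rounded half-up to one decimal, matching how diagnostic
sensitivity/specificity are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "MetricsError",
    "ConfusionMatrix",
    "ROCResult",
    "roc_auc",
    "auc_ci",
    "roc_points",
    "confusion_at_threshold",
    "confusion_rates",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at a fixed threshold; positive class = Treat."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise MetricsError(
                f"inconsistent ROC interval: {self.ci_low}, {self.auc}, {self.ci_high}"
            )


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricsError("scores and labels must be 1-D and aligned")
    pos = scores[labels == 1] if labels.dtype.kind in "biu" else scores[labels == "Treat"]
    neg = scores[labels == 0] if labels.dtype.kind in "biu" else scores[labels == "Control"]
    if pos.size == 0 or neg.size == 0:
        raise MetricsError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: (#concordant + 0.5 #ties) / (n_pos * n_neg)."""
    pos, neg = _split_scores(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = pos.size
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * neg.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def auc_ci(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """AUC with a confidence interval (DeLong by default, bootstrap optional)."""
    pos, neg = _split_scores(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise MetricsError("need >= 2 samples per class for a confidence interval")
    auc = roc_auc(scores, labels)
    if method == "delong":
        m, n = pos.size, neg.size
        tz = _midrank(np.concatenate([pos, neg]))
        tx, ty = _midrank(pos), _midrank(neg)
        v01 = (tz[:m] - tx) / n  # placement values of positives
        v10 = 1.0 - (tz[m:] - ty) / m  # placements of negatives
        var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, size=pos.size, replace=True)
            ns = rng.choice(neg, size=neg.size, replace=True)
            ranks = stats.rankdata(np.concatenate([ps, ns]))
            draws[b] = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
                pos.size * neg.size
            )
        alpha = 1.0 - level
        lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise MetricsError(f"unknown CI method {method!r}")
    return ROCResult(
        auc=auc,
        ci_low=float(min(max(lo, 0.0), auc)),
        ci_high=float(max(min(hi, 1.0), auc)),
        method=method,
    )


def roc_points(scores, labels) -> np.ndarray:
    """(fpr, tpr, threshold) triples over all distinct score cutoffs."""
    pos, neg = _split_scores(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    rows = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        rows.append((fpr, tpr, float(t)))
    return np.array(rows)


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally predictions (positive iff score >= threshold) against labels."""
    scores_arr = np.asarray(scores, dtype=float)
    if np.any((scores_arr < 0) | (scores_arr > 1)):
        raise MetricsError("scores must be probabilities in [0, 1]")
    pos, neg = _split_scores(scores, labels)
    return ConfusionMatrix(
        tp=int((pos >= threshold).sum()),
        fn=int((pos < threshold).sum()),
        tn=int((neg < threshold).sum()),
        fp=int((neg >= threshold).sum()),
    )


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def confusion_rates(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity and accuracy as percentages (1 decimal, half-up)."""
    if cm.tp + cm.fn == 0:
        raise MetricsError("sensitivity undefined: no positive samples (TP+FN = 0)")
    if cm.tn + cm.fp == 0:
        raise MetricsError("specificity undefined: no negative samples (TN+FP = 0)")
    return {
        "sensitivity": _round1(100.0 * cm.tp / (cm.tp + cm.fn)),
        "specificity": _round1(100.0 * cm.tn / (cm.tn + cm.fp)),
        "accuracy": _round1(100.0 * (cm.tp + cm.tn) / cm.total),
    }
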