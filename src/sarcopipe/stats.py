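"""Confusion-matrix metrics, ROC/AUC, group comparisons, tumor volume and
reader-vs-model cross-tabulation.

Sarcoma-group cases are positive, leiomyomas negative. The headline
statistic is SS-Avg = (sensitivity + specificity)/2 — balanced accuracy —
used because the two classes are far from balanced; when class sizes are
equal it coincides with ordinary accuracy. Percentages are reported at one
decimal with round-half-even.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "TumorGeometry",
    "metrics",
    "roc_auc",
    "compare_groups",
    "tumor_volume",
    "misdiagnosis_crosstab",
    "round1",
]


def round1(x: float) -> float:
    """One-decimal rounding, round-half-even (report convention)."""
    return float(round(x, 1))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN at the patient (or study) level."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, SS-Avg, sensitivity, specificity — all percentages."""

    accuracy: float
    ss_avg: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class TumorGeometry:
    """Tumor extents (length, width, height) in a common unit."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("tumor dimensions must be positive")


def metrics(counts: ConfusionCounts) -> MetricSet:
    """The four performance percentages from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); SS-Avg = (sensitivity+specificity)/2.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive cases: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative cases: specificity undefined")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    acc = (counts.tp + counts.tn) / counts.total
    return MetricSet(
        accuracy=100 * acc,
        ss_avg=100 * (sens + spec) / 2.0,
        sensitivity=100 * sens,
        specificity=100 * spec,
    )


def roc_auc(scores, labels, positive_label=None) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC over the full cut-point sweep.

    ``labels`` may be booleans, 0/1, or strings with ``positive_label``
    naming the positive class. Tied scores are grouped into a single
    cut-point. Returns ``(points, auc)`` where points is an array of
    (false positive rate, true positive rate) rows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive_label is not None:
        y = labels == positive_label
    else:
        y = labels.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def compare_groups(
    sample_a, sample_b, variance_rule: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``variance_rule``: ``student`` pools variances (equal-variance t-test),
    ``welch`` does not, ``auto`` runs an F-ratio pretest on the two sample
    variances at alpha=0.05 and picks Welch when it rejects equality.
    Returns ``(t, p)``; identical samples give (0, 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variance_rule == "auto":
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            variance_rule = "student"
        else:
            f = max(va, vb) / max(min(va, vb), 1e-300)
            dfn = len(a) - 1 if va >= vb else len(b) - 1
            dfd = len(b) - 1 if va >= vb else len(a) - 1
            p_var = 2 * min(_sps.f.sf(f, dfn, dfd), 1 - _sps.f.sf(f, dfn, dfd))
            variance_rule = "welch" if p_var < 0.05 else "student"
    if variance_rule not in ("student", "welch"):
        raise ValueError(f"unknown variance rule {variance_rule!r}")
    res = _sps.ttest_ind(a, b, equal_var=(variance_rule == "student"))
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both identical samples
        t, p = 0.0, 1.0
    return t, p


def tumor_volume(geometry: TumorGeometry, formula_mode: str = "as_printed") -> float:
    """Tumor volume from the three diameters.

    ``as_printed`` (default) uses (3/4)*pi*a*b*c with a,b,c the half-axes —
    the coefficient the source protocol prints. ``ellipsoid`` uses the
    geometric ellipsoid volume (4/3)*pi*a*b*c, a factor 16/9 larger. The
    printed coefficient is kept as the default for fidelity with the
    protocol; the ellipsoid mode is the geometrically correct alternative.
    """
    a = geometry.length / 2.0
    b = geometry.width / 2.0
    c = geometry.height / 2.0
    if formula_mode == "as_printed":
        return 0.75 * np.pi * a * b * c
    if formula_mode == "ellipsoid":
        return (4.0 / 3.0) * np.pi * a * b * c
    raise ValueError(f"unknown formula mode {formula_mode!r}")


def misdiagnosis_crosstab(
    model_calls: dict[str, list], reader_calls: dict[str, list], labels: dict[str, str]
) -> dict[str, str]:
    """Per-case agreement category between model ensembles and readers.

    ``model_calls[case]`` / ``reader_calls[case]`` are lists of binary calls
    (True/'positive'/1 = sarcoma call) from the ensemble sets and from the
    readers. A side "misdiagnoses" the case when strictly more than half of
    its calls are wrong. Categories: ``model_only``, ``readers_only``,
    ``both``, ``neither``.
    """
    if set(model_calls) != set(reader_calls) or set(model_calls) != set(labels):
        raise ValueError("case identifiers of calls and labels do not match")

    def majority_wrong(calls, truth_positive: bool) -> bool:
        wrong = sum(
            1
            for c in calls
            if (c in (True, 1, "positive")) != truth_positive
        )
        return wrong * 2 > len(calls)

    out = {}
    for case, label in labels.items():
        truth = label in ("sarcoma_group", "positive", 1, True)
        model_wrong = majority_wrong(model_calls[case], truth)
        reader_wrong = majority_wrong(reader_calls[case], truth)
        if model_wrong and reader_wrong:
            out[case] = "both"
        elif model_wrong:
            out[case] = "model_only"
        elif reader_wrong:
            out[case] = "readers_only"
        else:
            out[case] = "neither"
    return out
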