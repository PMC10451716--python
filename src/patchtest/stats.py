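"""Performance metrics and paired classifier-comparison tests.

Two classifiers evaluated on the same validation chambers are compared with
McNemar's test on their discordant predictions; classifiers compared under
repeated cross-validation use Alpaydin's combined 5x2 cv F-test, which is
F-distributed with (10, 5) degrees of freedom under the null of equal
performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classifier import PredictionRecord

METRIC_NAMES = ("f1", "accuracy", "specificity", "recall", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn)


def confusion_from_records(records: Sequence[PredictionRecord]) -> ConfusionCounts:
    tp = sum(r.true_label == "positive" and r.predicted_label == "positive" for r in records)
    fp = sum(r.true_label == "negative" and r.predicted_label == "positive" for r in records)
    tn = sum(r.true_label == "negative" and r.predicted_label == "negative" for r in records)
    fn = sum(r.true_label == "positive" and r.predicted_label == "negative" for r in records)
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """F1, accuracy, specificity, recall and precision from a confusion matrix.

    Ratios with a zero denominator are reported as NaN with a warning rather
    than silently as 0.
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    accuracy = (counts.tp + counts.tn) / counts.total
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        warnings.warn("f1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"f1": f1, "accuracy": accuracy, "specificity": specificity, "recall": recall, "precision": precision}


@dataclass(frozen=True)
class PairedOutcomes:
    """Discordant-pair evidence for two classifiers on the same chambers.

    ``b`` counts chambers classifier A got right and B wrong; ``c`` the
    converse; ``n`` the common evaluation size.
    """

    b: int
    c: int
    n: int

    def __post_init__(self) -> None:
        if self.b + self.c > self.n:
            raise ValueError("discordant pairs exceed total")


def paired_outcomes(a: Sequence[PredictionRecord], b: Sequence[PredictionRecord]) -> PairedOutcomes:
    """Align two record sets on chamber keys and count discordant pairs."""
    bmap = {r.key: r for r in b}
    if set(r.key for r in a) != set(bmap):
        raise ValueError("record sets evaluate different chambers")
    n_b = n_c = 0
    for ra in a:
        rb = bmap[ra.key]
        if ra.correct and not rb.correct:
            n_b += 1
        elif rb.correct and not ra.correct:
            n_c += 1
    return PairedOutcomes(n_b, n_c, len(a))


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    evidence: PairedOutcomes | np.ndarray | None = None


def mcnemar(outcomes: PairedOutcomes, mode: str = "auto") -> ComparisonResult:
    """McNemar's test on the discordant pairs of two paired classifiers.

    ``exact`` runs the two-sided binomial test of ``b`` successes in
    ``b + c`` trials at probability 0.5; ``chi2`` uses the
    continuity-corrected statistic ``(|b - c| - 1)^2 / (b + c)`` against
    chi-square(1).  ``auto`` picks exact when ``b + c < 25``.  With no
    discordant pairs there is no evidence either way and p = 1 by
    convention.
    """
    if mode not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown mode: {mode!r}")
    b, c = outcomes.b, outcomes.c
    if b + c == 0:
        warnings.warn("no discordant pairs; p = 1 by convention", RuntimeWarning, stacklevel=2)
        return ComparisonResult(0.0, 1.0, "mcnemar-degenerate", outcomes)
    if mode == "auto":
        mode = "exact" if b + c < 25 else "chi2"
    if mode == "exact":
        p = sps.binomtest(b, b + c, 0.5, alternative="two-sided").pvalue
        return ComparisonResult(float(min(b, c)), float(p), "mcnemar-exact", outcomes)
    stat = (abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(sps.chi2.sf(stat, df=1))
    return ComparisonResult(float(stat), p, "mcnemar-chi2", outcomes)


def five_by_two_ftest(differences: np.ndarray | Sequence[Sequence[float]]) -> ComparisonResult:
    """Alpaydin's combined 5x2 cv F-test.

    ``differences`` holds the performance difference ``p_ij`` of the two
    classifiers for repetition i (5 rows) and fold j (2 columns).  With
    per-repetition mean ``m_i`` and variance
    ``s_i^2 = (p_i1 - m_i)^2 + (p_i2 - m_i)^2``, the statistic

        F = (sum_ij p_ij^2) / (2 * sum_i s_i^2)

    follows F(10, 5) under the null.  If all fold variances are zero the
    two classifiers behaved identically on every fold and the statistic is
    undefined (NaN, with a warning).
    """
    d = np.asarray(differences, dtype=float)
    if d.shape != (5, 2):
        raise ValueError(f"expected a 5x2 array of differences, got shape {d.shape}")
    m = d.mean(axis=1, keepdims=True)
    s2 = ((d - m) ** 2).sum(axis=1)
    denom = 2.0 * s2.sum()
    if denom == 0.0:
        warnings.warn("all fold variances are zero; F statistic undefined", RuntimeWarning, stacklevel=2)
        return ComparisonResult(float("nan"), float("nan"), "five_by_two_f", d)
    f_stat = float((d**2).sum() / denom)
    p = float(sps.f.sf(f_stat, 10, 5))
    return ComparisonResult(f_stat, p, "five_by_two_f", d)


def aggregate_folds(
    per_fold_metrics: Sequence[Mapping[str, float]],
    per_fold_counts: Sequence[ConfusionCounts] | None = None,
) -> tuple[pd.DataFrame, ConfusionCounts | None]:
    """Mean +- sample standard deviation per metric; confusion counts summed.

    The per-metric spread uses the sample (ddof = 1) standard deviation over
    folds, the convention for reporting K-fold results.
    """
    if len(per_fold_metrics) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    if per_fold_counts is not None and len(per_fold_counts) != len(per_fold_metrics):
        raise ValueError("fold count mismatch between metrics and confusion matrices")
    names = list(per_fold_metrics[0])
    if any(set(m) != set(names) for m in per_fold_metrics):
        raise ValueError("inconsistent metric names across folds")
    rows = []
    for name in names:
        vals = np.array([m[name] for m in per_fold_metrics], dtype=float)
        rows.append({"metric": name, "mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals, ddof=1))})
    pooled = None
    if per_fold_counts is not None:
        pooled = per_fold_counts[0]
        for c in per_fold_counts[1:]:
            pooled = pooled + c
    return pd.DataFrame(rows), pooled
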