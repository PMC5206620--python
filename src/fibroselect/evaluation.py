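"""Diagnostic-performance statistics for single markers and classifiers.

ROC analysis with trapezoidal AUC (numerically identical to the
tie-corrected Mann-Whitney statistic U/(n1*n2)), Youden-style best cut-off
(maximising sensitivity + specificity), test-set-locked threshold transfer
to a validation cohort, combined random-forest classifiers, Spearman rank
correlation and the Mann-Whitney test.

Marker direction matters: disease raises most urinary mRNAs and serum
creatinine but lowers eGFR. ``direction="auto"`` orients each marker so
that its AUC is at least 0.5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import forest as rf
from .cohort import CohortTable

__all__ = [
    "RocCurve",
    "BinaryMetrics",
    "CorrelationResult",
    "TestResult",
    "roc_curve",
    "best_cutoff",
    "auc_band",
    "auc_confidence_interval",
    "binary_metrics",
    "classify_threshold",
    "locked_threshold_eval",
    "combined_classifier_eval",
    "spearman",
    "mann_whitney",
    "GREATER_IS_POSITIVE",
    "LESS_IS_POSITIVE",
]

GREATER_IS_POSITIVE = "greater_is_positive"
LESS_IS_POSITIVE = "less_is_positive"


@dataclass
class RocCurve:
    """Operating points (threshold, sensitivity, specificity) and AUC.

    Under ``greater_is_positive`` a sample is called positive when its
    score strictly exceeds the threshold; under ``less_is_positive`` when
    it falls strictly below. Thresholds are midpoints between consecutive
    distinct scores, plus -inf/+inf sentinels.
    """

    points: list[tuple[float, float, float]]
    auc: float
    best_cutoff: float
    direction: str


@dataclass(frozen=True)
class BinaryMetrics:
    """Confusion counts with accuracy, sensitivity and specificity."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")


def _curve_points(
    scores: np.ndarray, labels: np.ndarray
) -> list[tuple[float, float, float]]:
    """Operating points for greater-is-positive scores, high threshold first."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    distinct = np.flatnonzero(s_sorted[:-1] < s_sorted[1:])
    thresholds = [(s_sorted[i] + s_sorted[i + 1]) / 2.0 for i in distinct]
    points: list[tuple[float, float, float]] = [(math.inf, 0.0, 1.0)]
    cum_pos = np.cumsum(y_sorted)
    for i in reversed(range(len(thresholds))):
        cut = distinct[i]  # samples [0..cut] are <= threshold
        pos_below = cum_pos[cut]
        neg_below = (cut + 1) - pos_below
        tp = n_pos - pos_below
        tn = neg_below
        points.append((thresholds[i], tp / n_pos, tn / n_neg))
    points.append((-math.inf, 1.0, 0.0))
    return points


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = GREATER_IS_POSITIVE,
) -> RocCurve:
    """ROC curve with trapezoidal AUC and Youden-style best cut-off.

    The AUC equals the tie-corrected two-sample rank statistic
    U/(n1*n2) to machine precision. ``direction="auto"`` picks the
    orientation whose AUC is >= 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    _check_binary(labels)

    if direction == "auto":
        greater = roc_curve(scores, labels, GREATER_IS_POSITIVE)
        if greater.auc >= 0.5:
            return greater
        return roc_curve(scores, labels, LESS_IS_POSITIVE)
    if direction not in (GREATER_IS_POSITIVE, LESS_IS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")

    oriented = scores if direction == GREATER_IS_POSITIVE else -scores
    points = _curve_points(oriented, labels)
    if direction == LESS_IS_POSITIVE:
        points = [(-t, se, sp) for (t, se, sp) in points]

    # trapezoid over (FPR, TPR); ties sit on a single diagonal segment,
    # reproducing the average-rank U statistic
    fpr = np.array([1.0 - sp for (_, _, sp) in points])
    tpr = np.array([se for (_, se, _) in points])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    curve = RocCurve(points=points, auc=auc, best_cutoff=math.nan, direction=direction)
    curve.best_cutoff = best_cutoff(curve)
    return curve


def best_cutoff(curve: RocCurve) -> float:
    """Threshold maximising sensitivity + specificity.

    Ties break toward higher specificity, then toward the threshold
    calling more samples negative (the conservative operating point).
    """
    def sort_key(point: tuple[float, float, float]) -> tuple[float, float, float]:
        t, se, sp = point
        # threshold orientation flips with direction; "more negative calls"
        # is the higher threshold under greater_is_positive, lower under less
        t_pref = t if curve.direction == GREATER_IS_POSITIVE else -t
        return (se + sp, sp, t_pref)

    best = max(curve.points, key=sort_key)
    return best[0]


def auc_band(auc: float) -> str:
    """Qualitative AUC band: [0.6,0.7) poor, [0.7,0.8) moderate,
    [0.8,0.9) good, >=0.9 excellent; below 0.6 'uninformative'."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must be in [0, 1]")
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "moderate"
    if auc >= 0.6:
        return "poor"
    return "uninformative"


def auc_confidence_interval(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = GREATER_IS_POSITIVE,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the AUC (stratified resampling)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        aucs[b] = roc_curve(scores[idx], labels[idx], direction).auc
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha)))


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> BinaryMetrics:
    """Validated confusion counts; requires both classes non-empty."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if tp + fn < 1:
        raise ValueError("no positive samples (tp + fn = 0)")
    if tn + fp < 1:
        raise ValueError("no negative samples (tn + fp = 0)")
    return BinaryMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def classify_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    direction: str = GREATER_IS_POSITIVE,
) -> BinaryMetrics:
    """Confusion counts from a fixed cut-off applied to scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction == GREATER_IS_POSITIVE:
        called = scores > threshold
    elif direction == LESS_IS_POSITIVE:
        called = scores < threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    tp = int((called & (labels == 1)).sum())
    fp = int((called & (labels == 0)).sum())
    fn = int((~called & (labels == 1)).sum())
    tn = int((~called & (labels == 0)).sum())
    return binary_metrics(tp=tp, fp=fp, tn=tn, fn=fn)


def locked_threshold_eval(
    test: CohortTable,
    validation: CohortTable,
    marker: str,
    direction: str = "auto",
) -> tuple[RocCurve, BinaryMetrics]:
    """Derive a marker's best cut-off on the test cohort, apply it locked
    to the validation cohort.

    The validation cohort's labels are consulted only after the threshold
    is fixed, mirroring a prospective two-stage design.
    """
    test_scores = test.column(marker)
    curve = roc_curve(test_scores, test.labels, direction)
    val_scores = validation.column(marker)
    metrics = classify_threshold(
        val_scores, validation.labels, curve.best_cutoff, curve.direction
    )
    return curve, metrics


def combined_classifier_eval(
    test: CohortTable,
    validation: CohortTable,
    feature_sets: Sequence[Sequence[str]],
    params: rf.ForestParams | None = None,
    vote_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Train an RF per feature set on the test cohort; score the validation
    cohort. Returns one row per classifier with accuracy, sensitivity,
    specificity and the confusion counts.

    ``vote_cutoff`` is the fraction of tree votes for the positive class
    required to call a sample positive (0.5 = majority vote; ties go to
    the negative class).
    """
    params = params or rf.ForestParams()
    rows = []
    for features in feature_sets:
        features = list(features)
        X_train = test.feature_matrix(features)
        X_val = validation.feature_matrix(features)
        model = rf.train(X_train, test.labels, params, task=rf.CLASSIFICATION)
        _, frac = rf.predict(model, X_val)
        metrics = classify_threshold(
            frac, validation.labels, vote_cutoff, GREATER_IS_POSITIVE
        )
        rows.append(
            {
                "classifier": " + ".join(features),
                "n_features": len(features),
                "accuracy": metrics.accuracy,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "tp": metrics.tp,
                "fp": metrics.fp,
                "tn": metrics.tn,
                "fn": metrics.fn,
            }
        )
    return pd.DataFrame(rows)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    r is the Pearson correlation of the rank vectors; the two-sided p-value
    uses the t approximation t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom (adequate for the cohort sizes this package targets).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero variance in one of the variables")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    r = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_value=min(p, 1.0) if p > 0 else p, n=n)


def _exact_mw_p(u: float, n1: int, n2: int, ranks_pooled: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group-1 rank assignments."""
    n = n1 + n2
    base = n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    observed_dev = abs(u - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        r1 = sum(ranks_pooled[list(combo)])
        u_perm = r1 - base
        total += 1
        if abs(u_perm - mean_u) >= observed_dev - 1e-9:
            count += 1
    return count / total


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney test.

    U is computed from average-rank sums. The p-value is exact (full
    enumeration of rank assignments) when n1 + n2 <= 12 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections is used. Identical groups give p = 1 (U = n1*n2/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled, method="average")
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    n = n1 + n2

    if n <= 12 and not has_ties:
        p = _exact_mw_p(u, n1, n2, ranks)
    else:
        mean_u = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0.0:
            p = 1.0
        else:
            z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
            z = max(z, 0.0)
            p = float(2.0 * stats.norm.sf(z))
    return TestResult(statistic=float(u), p_value=min(p, 1.0), n1=n1, n2=n2)
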