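"""Evaluation statistics for welfare classifiers.

Accuracy is the usual confusion-matrix fraction in percent; agreement is
Cohen's kappa; the divergence score is a cross-entropy between the target
class distribution P and the estimate Q. Note the adopted cross-entropy
convention: the default weights each term by the *estimate*,

    H(P, Q) = - sum_i Q_i log(P_i),

with the textbook target-weighted form (- sum_i P_i log Q_i) available via
``convention="target_weighted"``. Logarithms are base 2 by default.

Decision thresholds: a classification is considered relevant when accuracy
is at least 75 %, applicable when kappa is at least 0.70, and acceptably
fitted when the cross-entropy is at most 0.2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import labels

ACCURACY_BAR = 75.0  # percent
KAPPA_BAR = 0.70
CROSS_ENTROPY_BAR = 0.2


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with distress as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMatrix:
    """Count the confusion matrix over {distress, normal} labels."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if not y_true:
        raise ValueError("cannot build a confusion matrix from empty label sequences")
    bad = set(y_true) | set(y_pred)
    bad -= set(labels.BINARY_LABELS)
    if bad:
        raise ValueError(f"unknown label(s) {sorted(bad)}; expected {labels.BINARY_LABELS}")
    tp = sum(t == labels.DISTRESS and p == labels.DISTRESS for t, p in zip(y_true, y_pred))
    tn = sum(t == labels.NORMAL and p == labels.NORMAL for t, p in zip(y_true, y_pred))
    fp = sum(t == labels.NORMAL and p == labels.DISTRESS for t, p in zip(y_true, y_pred))
    fn = sum(t == labels.DISTRESS and p == labels.NORMAL for t, p in zip(y_true, y_pred))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent correct: 100 * (TP + TN) / (TP + FP + FN + TN)."""
    return 100.0 * (cm.tp + cm.tn) / cm.total


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the confusion-matrix marginals.

    (p_o - p_e) / (1 - p_e); returns 0.0 for the degenerate all-one-cell
    case where chance agreement p_e = 1.
    """
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_pos_true = (cm.tp + cm.fn) / n
    p_pos_pred = (cm.tp + cm.fp) / n
    p_e = p_pos_true * p_pos_pred + (1 - p_pos_true) * (1 - p_pos_pred)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1 - p_e)


def cross_entropy(
    p: Sequence[float],
    q: Sequence[float],
    base: float = 2.0,
    convention: str = "estimate_weighted",
) -> float:
    """Cross-entropy between target distribution P and estimate Q.

    ``estimate_weighted`` (default): H = -sum_i Q_i log(P_i).
    ``target_weighted``: the textbook H = -sum_i P_i log(Q_i).
    Terms with zero weight contribute 0; a zero probability under the log
    with positive weight yields +inf.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, d in (("P", p), ("Q", q)):
        if d.ndim != 1 or len(d) != len(p):
            raise ValueError("P and Q must be one-dimensional with a common support")
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError(f"{name} entries must lie in [0, 1]")
        if abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {d.sum():.12f})")
    if base <= 1:
        raise ValueError("log base must exceed 1")
    if convention == "estimate_weighted":
        weights, inner = q, p
    elif convention == "target_weighted":
        weights, inner = p, q
    else:
        raise ValueError("convention must be 'estimate_weighted' or 'target_weighted'")
    total = 0.0
    for w, x in zip(weights, inner):
        if w == 0:
            continue
        if x == 0:
            return math.inf
        total -= w * math.log(x) / math.log(base)
    return float(total)


def log_loss_score(
    y_true: Sequence[str],
    prob_distress: Sequence[float],
    base: float = 2.0,
    eps: float = 1e-15,
) -> float:
    """Per-instance cross-entropy (log loss) of probabilistic predictions.

    Mean of ``-log q_i(y_i)`` over instances, where ``q_i`` is the
    predicted probability the model assigns to the true class (the
    target-weighted per-instance form; the instance-level target is a point
    mass, under which the estimate-weighted form degenerates).
    Probabilities are clipped to [eps, 1 - eps].
    """
    y_true = list(y_true)
    q = np.asarray(prob_distress, dtype=float)
    if len(y_true) != len(q):
        raise ValueError("one probability per instance is required")
    if not y_true:
        raise ValueError("empty label sequence")
    bad = set(y_true) - set(labels.BINARY_LABELS)
    if bad:
        raise ValueError(f"unknown label(s) {sorted(bad)}")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    q_true = np.where([t == labels.DISTRESS for t in y_true], q, 1 - q)
    q_true = np.clip(q_true, eps, 1 - eps)
    return float(-np.mean(np.log(q_true) / math.log(base)))


def label_distribution(y: Sequence[str]) -> np.ndarray:
    """Empirical (distress, normal) class distribution of a label sequence."""
    y = list(y)
    if not y:
        raise ValueError("empty label sequence")
    n = len(y)
    return np.array([y.count(labels.DISTRESS) / n, y.count(labels.NORMAL) / n])


def min_max_normalize(values: Sequence[float]) -> np.ndarray:
    """Proportional rescaling to [0, 1]: (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant vector: min-max scaling is undefined")
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    significant: bool


def two_group_t_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test (Welch by default; pooled-variance
    Student via ``equal_var=True``), significant when p < alpha."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


@dataclass(frozen=True)
class EvalReport:
    """Metrics plus pass/fail flags against the relevance thresholds."""

    accuracy: float  # percent
    kappa: float
    cross_entropy: float
    confusion: ConfusionMatrix | None = None

    @property
    def pass_flags(self) -> dict[str, bool]:
        return {
            "accuracy": bool(self.accuracy >= ACCURACY_BAR),
            "kappa": bool(self.kappa >= KAPPA_BAR),
            "cross_entropy": bool(self.cross_entropy <= CROSS_ENTROPY_BAR),
        }

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accuracy_pct": self.accuracy,
            "kappa": self.kappa,
            "cross_entropy": self.cross_entropy,
            "pass_flags": self.pass_flags,
            "passed": self.passed,
        }
        if self.confusion is not None:
            payload["confusion"] = {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    prob_distress: Sequence[float] | None = None,
    base: float = 2.0,
    convention: str = "estimate_weighted",
) -> EvalReport:
    """Full report from label sequences.

    With ``prob_distress`` (one predicted distress probability per
    instance) the cross-entropy is the per-instance log loss; without it,
    the empirical class distribution of the true labels (target P) is
    compared against that of the predictions (estimate Q) under the chosen
    convention.
    """
    cm = confusion(y_true, y_pred)
    if prob_distress is not None:
        h = log_loss_score(y_true, prob_distress, base=base)
    else:
        h = cross_entropy(
            label_distribution(y_true), label_distribution(y_pred), base=base, convention=convention
        )
    return EvalReport(accuracy=accuracy(cm), kappa=kappa(cm), cross_entropy=h, confusion=cm)


def compare_classifiers(
    table: pd.DataFrame,
    methods: Sequence[str] = ("knn", "decision_tree", "random_forest"),
    train_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Train each method on the same split seed and tabulate held-out
    metrics with pass flags (one row per classifier)."""
    from .welfare_classifier import holdout_predictions, train_classifier

    rows = []
    for method in methods:
        model = train_classifier(table, method=method, train_fraction=train_fraction, seed=seed)
        preds = holdout_predictions(model, table)
        rep = evaluate_predictions(
            preds["true_label"], preds["predicted_label"], preds["prob_distress"]
        )
        rows.append(
            {
                "classifier": method,
                "accuracy_pct": rep.accuracy,
                "kappa": rep.kappa,
                "cross_entropy": rep.cross_entropy,
                "accuracy_ok": rep.pass_flags["accuracy"],
                "kappa_ok": rep.pass_flags["kappa"],
                "cross_entropy_ok": rep.pass_flags["cross_entropy"],
            }
        )
    return pd.DataFrame(rows)
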