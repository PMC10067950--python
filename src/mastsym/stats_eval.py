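"""Paired diagnostic accuracy statistics.

Metrics follow radiology reader-study practice: each ear is one
observation.  The per-ear 3-class predictions are dichotomized (negative if
the normal category holds the highest probability, else positive) with the
continuous positive score ``1 - p(normal)``; AUC is the Mann-Whitney
statistic of that score, with DeLong structural-component confidence
intervals and one-sided DeLong tests for paired model comparisons.
Sensitivity, specificity and total (3-category) accuracy carry exact
Clopper-Pearson intervals, and paired sensitivity/specificity comparisons
use McNemar's test on discordant counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .labels import BilateralLabel, dichotomize_label, dichotomize_prediction
from .network import BilateralPrediction

__all__ = [
    "Proportion",
    "DiagnosticReport",
    "roc_auc",
    "delong_ci",
    "delong_compare_one_sided",
    "clopper_pearson",
    "mcnemar",
    "evaluate",
]


# ---------------------------------------------------------------------------
# ROC / AUC


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both classes must be present to compute AUC")
    return s[y == 1], s[y == 0]


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over (positive, negative) pairs of
    [s_pos > s_neg] + 0.5 [tie]."""
    x, y = _split_scores(scores, labels)
    v10, _ = _placements(x, y)
    return float(v10.mean())


def _placements(x: np.ndarray, y: np.ndarray):
    """DeLong structural components.

    ``V10[i]`` is the placement of positive score i among the negatives,
    ``V01[j]`` the placement of negative score j among the positives; both
    use midranks so ties count one half.
    """
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    r_all = sps.rankdata(combined)
    r_x = sps.rankdata(x)
    r_y = sps.rankdata(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    return v10, v01


def delong_ci(scores, labels, alpha: float = 0.05):
    """AUC with a DeLong normal-approximation confidence interval,
    truncated to [0, 1].  Returns ``(auc, lo, hi)``."""
    x, y = _split_scores(scores, labels)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("DeLong variance needs at least two members per class")
    v10, v01 = _placements(x, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; collapsing CI to the point estimate",
                      stacklevel=2)
        return auc, auc, auc
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_compare_one_sided(scores_a, scores_b, labels) -> float:
    """One-sided DeLong test for two correlated ROC curves on the same
    subjects; alternative: AUC of ``scores_a`` is greater than AUC of
    ``scores_b``.  Returns the upper-tail p-value."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have the same length")
    xa, ya = _split_scores(sa, labels)
    xb, yb = _split_scores(sb, labels)
    v10a, v01a = _placements(xa, ya)
    v10b, v01b = _placements(xb, yb)
    diff = float(v10a.mean() - v10b.mean())
    var = (v10a - v10b).var(ddof=1) / len(xa) + (v01a - v01b).var(ddof=1) / len(ya)
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.5
        return 0.0 if diff > 0 else 1.0
    z = diff / np.sqrt(var)
    return float(sps.norm.sf(z))


# ---------------------------------------------------------------------------
# binomial statistics


def clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Exact (Beta-quantile) binomial confidence interval.

    Returns ``(point, lo, hi)`` as proportions; ``lo = 0`` when ``k = 0``
    and ``hi = 1`` when ``k = n``.
    """
    k, n = int(k), int(n)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo = float(sps.beta.ppf(alpha / 2, k, n - k + 1)) if k > 0 else 0.0
    hi = float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k)) if k < n else 1.0
    return k / n, lo, hi


def mcnemar(b: int, c: int, exact_threshold: int = 25) -> float:
    """Two-sided McNemar test from the two discordant counts.

    Exact binomial when ``b + c`` is below ``exact_threshold``, otherwise
    continuity-corrected chi-square.  ``b = c = 0`` returns p = 1 with a
    degenerate-case warning.
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b == 0 and c == 0:
        warnings.warn("no discordant pairs; McNemar p-value is degenerate (1.0)",
                      stacklevel=2)
        return 1.0
    exact = (b + c) < exact_threshold
    res = _sm_mcnemar(np.array([[0, b], [c, 0]]), exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# report assembly


@dataclass(frozen=True)
class Proportion:
    """A proportion with its counts and exact 95% CI (all as fractions)."""

    k: int
    n: int
    point: float
    lo: float
    hi: float

    @classmethod
    def from_counts(cls, k: int, n: int, alpha: float = 0.05) -> "Proportion":
        point, lo, hi = clopper_pearson(k, n, alpha)
        return cls(k, n, point, lo, hi)

    def pct(self) -> str:
        return (f"{100 * self.point:.1f}% ({self.k}/{self.n}, "
                f"{100 * self.lo:.1f}-{100 * self.hi:.1f}%)")


def _severity_argmax(p: np.ndarray) -> int:
    # ties resolve toward the higher-severity category
    return int(2 - np.argmax(p[::-1]))


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-ear diagnostic performance of one model on one test set."""

    n_ears: int
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: Proportion
    specificity: Proportion
    accuracy: Proportion
    confusion: np.ndarray  # 3x3, rows true category, cols predicted
    comparisons: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Diagnostic report ({self.n_ears} ears)",
            f"  AUC          {self.auc:.3f} (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})",
            f"  Sensitivity  {self.sensitivity.pct()}",
            f"  Specificity  {self.specificity.pct()}",
            f"  Accuracy     {self.accuracy.pct()}",
            "  Confusion (rows: true 0/1/2, cols: predicted):",
        ]
        for row in self.confusion:
            lines.append("    " + "  ".join(f"{int(v):4d}" for v in row))
        for name, comp in self.comparisons.items():
            lines.append(f"  vs {name}:")
            for key, p in comp.items():
                lines.append(f"    {key:24s} p = {p:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_ears": self.n_ears,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": vars(self.sensitivity).copy(),
            "specificity": vars(self.specificity).copy(),
            "accuracy": vars(self.accuracy).copy(),
            "confusion": self.confusion.tolist(),
            "comparisons": self.comparisons,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _per_ear(predictions, labels):
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels are misaligned")
    probs, cats = [], []
    for pred, label in zip(predictions, labels):
        if label.excluded:
            raise ValueError(f"subject {label.subject_id!r} is excluded from evaluation")
        probs += [np.asarray(pred.right_probs), np.asarray(pred.left_probs)]
        cats += [int(label.right), int(label.left)]
    return probs, np.array(cats)


def ear_scores(predictions, labels):
    """Flatten subject predictions to per-ear binary truths, outcomes and
    positive-class scores (right ear then left ear per subject)."""
    probs, cats = _per_ear(predictions, labels)
    truth = np.array([dichotomize_label(c) for c in cats])
    outcome = np.empty(len(probs), dtype=int)
    score = np.empty(len(probs))
    for i, p in enumerate(probs):
        outcome[i], score[i] = dichotomize_prediction(p)
    return truth, outcome, score


def evaluate(
    predictions: list[BilateralPrediction],
    labels: list[BilateralLabel],
    comparators: dict[str, list[BilateralPrediction]] | None = None,
) -> DiagnosticReport:
    """Assemble the full diagnostic report for aligned per-subject
    predictions; each subject contributes two ears.

    ``comparators`` maps a name to another model's predictions on the same
    subjects; each contributes a one-sided DeLong AUC p-value (alternative:
    this model's AUC is greater) and McNemar p-values for sensitivity and
    specificity.
    """
    probs, cats = _per_ear(predictions, labels)
    truth, outcome, score = ear_scores(predictions, labels)

    confusion = np.zeros((3, 3), dtype=int)
    for p, c in zip(probs, cats):
        confusion[c, _severity_argmax(p)] += 1

    pos, neg = truth == 1, truth == 0
    tp = int(np.sum(outcome[pos] == 1))
    tn = int(np.sum(outcome[neg] == 0))
    auc, lo, hi = delong_ci(score, truth)

    comparisons: dict[str, dict[str, float]] = {}
    for name, other in (comparators or {}).items():
        o_truth, o_outcome, o_score = ear_scores(other, labels)
        if not np.array_equal(o_truth, truth):
            raise ValueError(f"comparator {name!r} is not paired with the same ears")
        se_b = int(np.sum((outcome == 1) & (o_outcome == 0) & pos))
        se_c = int(np.sum((outcome == 0) & (o_outcome == 1) & pos))
        sp_b = int(np.sum((outcome == 0) & (o_outcome == 1) & neg))
        sp_c = int(np.sum((outcome == 1) & (o_outcome == 0) & neg))
        comparisons[name] = {
            "delong_auc_greater": delong_compare_one_sided(score, o_score, truth),
            "mcnemar_sensitivity": mcnemar(se_b, se_c),
            "mcnemar_specificity": mcnemar(sp_b, sp_c),
        }

    return DiagnosticReport(
        n_ears=len(truth),
        auc=auc,
        auc_ci=(lo, hi),
        sensitivity=Proportion.from_counts(tp, int(pos.sum())),
        specificity=Proportion.from_counts(tn, int(neg.sum())),
        accuracy=Proportion.from_counts(int(np.trace(confusion)), int(confusion.sum())),
        confusion=confusion,
        comparisons=comparisons,
    )
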