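"""Identification-rate metrics, ROC/AUC and multi-network comparison.

Conventions: rest is the negative class, clench the positive class.
The five identification-rate metrics are

    accuracy    = (TN + TP) / (TN + TP + FN + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (FP + TN)
    precision   = TP / (FP + TP)
    F-value     = 2 * recall * precision / (recall + precision)

Fold aggregation is the unweighted (macro) mean with the sample SD.
The pooled ROC uses the clench-class scores of all folds; the AUC 95% CI
and the p-value against AUC = 0.5 come from DeLong's covariance estimate.
Network accuracies (correct/total counts) are compared pairwise with
Ryan's stepwise procedure on two-proportion chi-square tests.

A metric whose denominator is zero is reported as NaN (flagged), never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .classifier import PredictionSet


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise EvaluationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def correct(self) -> int:
        return self.tn + self.tp


def confusion_counts(preds: PredictionSet) -> ConfusionCounts:
    df = preds.frame
    return ConfusionCounts(
        tn=int(((df["label"] == "rest") & (df["pred"] == "rest")).sum()),
        fp=int(((df["label"] == "rest") & (df["pred"] == "clench")).sum()),
        fn=int(((df["label"] == "clench") & (df["pred"] == "rest")).sum()),
        tp=int(((df["label"] == "clench") & (df["pred"] == "clench")).sum()),
    )


@dataclass(frozen=True)
class MetricSet:
    """The five identification-rate metrics as fractions in [0, 1]."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f_value: float

    def as_percent_row(self) -> dict[str, float]:
        """Values at the table's printing precision (%, F to 3 decimals)."""
        return {
            "accuracy": round(100 * self.accuracy, 1),
            "recall": round(100 * self.recall, 1),
            "specificity": round(100 * self.specificity, 1),
            "precision": round(100 * self.precision, 1),
            "f_value": round(self.f_value, 3),
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def f_value(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (both as fractions or both %)."""
    return _ratio(2.0 * recall * precision, recall + precision)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    recall = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.fp + c.tp)
    return MetricSet(
        accuracy=_ratio(c.tn + c.tp, c.total),
        recall=recall,
        specificity=_ratio(c.tn, c.fp + c.tn),
        precision=precision,
        f_value=f_value(recall, precision),
    )


def aggregate_folds(per_fold: list[MetricSet]) -> dict[str, tuple[float, float]]:
    """Macro mean and sample SD (ddof=1) of each metric over folds."""
    if len(per_fold) < 2:
        raise EvaluationError("need >= 2 folds to aggregate")
    out = {}
    for name in ("accuracy", "recall", "specificity", "precision", "f_value"):
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


# --------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval

@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int


def auc_pairwise(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Brute-force Mann-Whitney AUC: fraction of (pos, neg) pairs ordered
    correctly, ties counting one half. O(n_pos * n_neg); oracle-grade."""
    sp = np.asarray(scores_pos, float)[:, None]
    sn = np.asarray(scores_neg, float)[None, :]
    wins = (sp > sn).sum() + 0.5 * (sp == sn).sum()
    return float(wins / (sp.size * sn.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores_pos: np.ndarray, scores_neg: np.ndarray) -> tuple[float, float]:
    """(AUC, variance of AUC) by DeLong's structural-components estimator."""
    m, n = len(scores_pos), len(scores_neg)
    all_scores = np.concatenate([scores_pos, scores_neg])
    r_all = _midrank(all_scores)
    r_pos = _midrank(scores_pos)
    r_neg = _midrank(scores_neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # per-positive components
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per-negative components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(preds: PredictionSet, alpha: float = 0.05) -> ROCResult:
    df = preds.frame
    y = (df["label"] == "clench").to_numpy()
    scores = df["score"].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc, var = delong_variance(scores[y], scores[~y])
    se = math.sqrt(var)
    z = stats.norm.ppf(1 - alpha / 2)
    if se > 0:
        p = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCResult(
        fpr=fpr, tpr=tpr, auc=auc,
        ci_low=max(0.0, auc - z * se), ci_high=min(1.0, auc + z * se),
        p_value=float(p), n_pos=int(y.sum()), n_neg=int((~y).sum()),
    )


# --------------------------------------------------------------------------
# Ryan's stepwise comparison of k proportions

@dataclass(frozen=True)
class PairDecision:
    name_a: str
    name_b: str
    p_raw: float
    alpha_adjusted: float
    significant: bool
    span: int


def _two_proportion_chi2(c1: int, n1: int, c2: int, n2: int) -> float:
    """Two-sided p of a two-proportion test without continuity correction.

    Pooled z-test, identical to the 2x2 chi-square; degenerate pooled
    proportions (all correct or all incorrect) give p = 1.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= c1 <= n1 and 0 <= c2 <= n2):
        raise EvaluationError("invalid proportion counts")
    p1, p2 = c1 / n1, c2 / n2
    pooled = (c1 + c2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def ryan_compare(counts: dict[str, tuple[int, int]],
                 alpha: float = 0.05) -> list[PairDecision]:
    """Stepwise pairwise comparison of k correct/total proportions.

    Proportions are rank-ordered; a pair spanning m adjacent ranks is
    tested at the adjusted level alpha' = 2*alpha / (k * m). Testing runs
    from the widest span inward; if a wider pair is not significant, the
    pairs nested inside it are declared not significant without testing
    (standard stepwise blocking).
    """
    if len(counts) < 2:
        raise EvaluationError("need >= 2 networks to compare")
    for name, (c, n) in counts.items():
        if n <= 0 or not 0 <= c <= n:
            raise EvaluationError(f"invalid counts for {name}: {c}/{n}")
    k = len(counts)
    ordered = sorted(counts, key=lambda s: counts[s][0] / counts[s][1])
    rank = {name: i for i, name in enumerate(ordered)}
    blocked: set[tuple[str, str]] = set()
    decisions: list[PairDecision] = []
    pairs = sorted(
        ((a, b) for i, a in enumerate(ordered) for b in ordered[i + 1:]),
        key=lambda ab: -(rank[ab[1]] - rank[ab[0]]),
    )
    for a, b in pairs:
        span = rank[b] - rank[a] + 1
        alpha_adj = 2 * alpha / (k * span)
        if (a, b) in blocked:
            decisions.append(PairDecision(a, b, math.nan, alpha_adj, False, span))
            continue
        ca, na = counts[a]
        cb, nb = counts[b]
        p = _two_proportion_chi2(ca, na, cb, nb)
        significant = p < alpha_adj
        decisions.append(PairDecision(a, b, p, alpha_adj, significant, span))
        if not significant:
            inner = ordered[rank[a]:rank[b] + 1]
            for i, x in enumerate(inner):
                for y2 in inner[i + 1:]:
                    blocked.add((x, y2))
    return decisions


# --------------------------------------------------------------------------
# report helpers

def metrics_report(per_fold: list[MetricSet],
                   fold_names: list[str] | None = None) -> pd.DataFrame:
    """Table of per-fold rows plus the Average +/- SD row (printed precision)."""
    names = fold_names or [f"Group {chr(65 + i)}" for i in range(len(per_fold))]
    rows = [dict(group=n, **m.as_percent_row()) for n, m in zip(names, per_fold)]
    agg = aggregate_folds(per_fold)
    avg_row = {"group": "Average"}
    sd_row = {"group": "SD"}
    for key, (mean, sd) in agg.items():
        scale = 1.0 if key == "f_value" else 100.0
        nd = 3 if key == "f_value" else 1
        avg_row[key] = round(scale * mean, nd)
        sd_row[key] = round(scale * sd, nd)
    return pd.DataFrame(rows + [avg_row, sd_row])


def micro_accuracy(per_fold_counts: list[ConfusionCounts]) -> float:
    """Pooled accuracy: sum of correct over sum of totals."""
    correct = sum(c.correct for c in per_fold_counts)
    total = sum(c.total for c in per_fold_counts)
    return _ratio(correct, total)
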