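"""ROC analysis, threshold selection and transfer, and 2x2 diagnostic metrics.

The positive call is score >= threshold throughout.  The optimal cutoff
maximizes Youden's J = sensitivity + specificity - 1 (ties toward higher
specificity, then lower threshold).  Odds-ratio confidence intervals use
the Woolf log method, relative-risk intervals the Katz log method; both
reproduce standard printed 2x2 epidemiology tables exactly.  Correlated
AUCs are compared with DeLong's nonparametric structural-components test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class RocError(ValueError):
    """Scores/labels unusable for ROC analysis (e.g. a single class)."""


@dataclass
class RocCurve:
    thresholds: np.ndarray  # strictly increasing candidate cutoffs
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_index: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class ContingencyMetrics:
    """Counts and metrics of the 2x2 (call x outcome) table.

    a = called positive & converted, b = called positive & stable,
    c = called negative & converted, d = called negative & stable.
    """

    a: int
    b: int
    c: int
    d: int
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    odds_ratio: float
    or_ci: tuple[float, float]
    relative_risk: float
    rr_ci: tuple[float, float]
    haldane_correction: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0], "or_ci_high": self.or_ci[1],
            "relative_risk": self.relative_risk,
            "rr_ci_low": self.rr_ci[0], "rr_ci_high": self.rr_ci[1],
        }


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "P-MCI").astype(int)
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise RocError(f"labels must be binary, got {np.unique(y)}")
    return y


def roc_curve(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC curve over midpoint thresholds with sentinels outside the score
    range; AUC by the trapezoidal rule (equals the Mann-Whitney concordance
    probability with ties counted half)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise RocError("both classes must be present")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    calls = s[None, :] >= thresholds[:, None]
    tp = (calls & (y == 1)).sum(axis=1)
    tn = (~calls & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg

    # descending threshold order walks the ROC staircase from (0,0) to (1,1)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    opt_idx = _youden_index(thresholds, sens, spec)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[opt_idx]),
        optimal_index=int(opt_idx),
    )


def _youden_index(thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray) -> int:
    # tie rules: max J, then max specificity, then min threshold
    j = sens + spec - 1.0
    best_key = None
    best_idx = 0
    for i in range(len(thresholds)):
        key = (j[i], spec[i], -thresholds[i])
        if best_key is None or key > best_key:
            best_key = key
            best_idx = i
    return best_idx


def optimal_threshold(curve: RocCurve) -> float:
    """The Youden-optimal cutoff of a fitted curve."""
    idx = _youden_index(curve.thresholds, curve.sensitivity, curve.specificity)
    return float(curve.thresholds[idx])


def contingency_metrics(a: int, b: int, c: int, d: int) -> ContingencyMetrics:
    """Diagnostic metrics of the 2x2 table.

    OR CI: Woolf, exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    RR CI: Katz, exp(ln RR +/- 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    A zero cell triggers the Haldane 0.5 continuity correction for the
    ratio estimates and CIs (flagged); the proportions use the raw counts.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_pos = a + c
    n_neg = b + d
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty table")
    sens = a / n_pos if n_pos else math.nan
    spec = d / n_neg if n_neg else math.nan
    acc = (a + d) / total
    bal = (sens + spec) / 2.0

    haldane = min(a, b, c, d) == 0
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if haldane else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se_or = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    or_ci = (or_ * math.exp(-1.96 * se_or), or_ * math.exp(1.96 * se_or))
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se_rr = math.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
    rr_ci = (rr * math.exp(-1.96 * se_rr), rr * math.exp(1.96 * se_rr))

    return ContingencyMetrics(
        a=a, b=b, c=c, d=d,
        sensitivity=sens, specificity=spec,
        accuracy=acc, balanced_accuracy=bal,
        odds_ratio=or_, or_ci=or_ci,
        relative_risk=rr, rr_ci=rr_ci,
        haldane_correction=haldane,
    )


def transfer_threshold(
    threshold: float, scores: Sequence[float], labels: Sequence
) -> ContingencyMetrics:
    """Apply a fixed cutoff (e.g. one learned in a discovery cohort) to new
    scores: call positive at score >= threshold, then tabulate."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    calls = s >= threshold
    a = int(np.sum(calls & (y == 1)))
    b = int(np.sum(calls & (y == 0)))
    c = int(np.sum(~calls & (y == 1)))
    d = int(np.sum(~calls & (y == 0)))
    return contingency_metrics(a, b, c, d)


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    variance: float


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative) with
    half-credit ties, and the AUC (their common mean)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def compare_aucs(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> DeLongResult:
    """DeLong's test for two AUCs measured on the same subjects.

    Returns the z statistic (AUC_a - AUC_b over its DeLong standard error)
    and a two-sided normal p-value.  Degenerate zero variance (e.g.
    identical or shift-equivalent score vectors) yields z = 0, p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary(labels)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score vectors and labels must have equal length")
    if y.sum() == 0 or y.sum() == len(y):
        raise RocError("both classes must be present")

    pos_a, neg_a = sa[y == 1], sa[y == 0]
    pos_b, neg_b = sb[y == 1], sb[y == 0]
    v10a, v01a, auc_a = _placements(pos_a, neg_a)
    v10b, v01b, auc_b = _placements(pos_b, neg_b)

    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, max(var, 0.0))
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(z), float(p), float(var))


def ranking_table(metrics: pd.DataFrame, higher_is_better: dict[str, bool] | None = None) -> pd.DataFrame:
    """Rank predictors on each metric column (1 = best, ties share the lower
    rank number).  ``metrics`` has one row per predictor; all columns are
    ranked descending unless ``higher_is_better`` says otherwise.

    Returns a frame with the original values plus a ``rank_<metric>`` column
    per metric, mirroring the layout of cross-cohort comparison tables.
    """
    if len(metrics) < 2:
        raise ValueError("ranking needs at least two predictors")
    higher_is_better = higher_is_better or {}
    out = metrics.copy()
    for col in metrics.columns:
        ascending = not higher_is_better.get(col, True)
        out[f"rank_{col}"] = (
            metrics[col].rank(ascending=ascending, method="min").astype(int)
        )
    return out
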