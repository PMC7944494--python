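"""Empirical ROC curves, AUC and DeLong comparison tests.

The AUC is the Mann-Whitney probability P(score_case > score_control) with
half credit for ties, identical to the trapezoidal area under the
tie-grouped empirical curve; for a binary rule it reduces to
(sensitivity + specificity)/2.  Standard errors and the paired/unpaired
z-tests use DeLong's structural components (placement values), the
standard nonparametric treatment of correlated empirical AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "ROCCurve",
    "AUCResult",
    "SingleClassError",
    "roc_curve",
    "auc",
    "delong_paired_test",
    "delong_unpaired_test",
    "plot_roc",
]


class SingleClassError(ValueError):
    """Outcome vector contains only one class."""


@dataclass(frozen=True)
class ROCCurve:
    """Stepwise empirical ROC curve.

    ``thresholds`` are the unique score values in descending order; point
    ``i + 1`` of (``fpr``, ``tpr``) is the operating point of the rule
    "positive iff score >= thresholds[i]".  Point 0 is (0, 0), the
    all-negative policy; the last point is (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def _split(scores: Sequence[float], outcomes: Sequence) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must be aligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("both outcome classes must be present")
    return pos, neg


def roc_curve(scores: Sequence[float], outcomes: Sequence) -> ROCCurve:
    """Tie-grouped empirical ROC curve; one step per unique score value."""
    pos, neg = _split(scores, outcomes)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    ss, yy = s[order], y[order]
    # last index of each tie block
    last = np.nonzero(np.append(ss[1:] != ss[:-1], True))[0]
    tp = np.cumsum(yy)[last]
    fp = (last + 1) - tp
    thresholds = ss[last]
    tpr = np.concatenate([[0.0], tp / pos.size])
    fpr = np.concatenate([[0.0], fp / neg.size])
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr,
                    n_pos=int(pos.size), n_neg=int(neg.size))


@dataclass(frozen=True)
class AUCResult:
    """AUC with DeLong standard error and Wald 95% CI truncated to [0, 1]."""

    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    ``v10[i]``: fraction of controls below case i (ties half); ``v01[j]``:
    fraction of cases above control j (ties half).  mean(v10) = AUC.
    """
    ns = np.sort(neg)
    left = np.searchsorted(ns, pos, side="left")
    right = np.searchsorted(ns, pos, side="right")
    v10 = (left + right) / (2.0 * neg.size)
    ps = np.sort(pos)
    left = np.searchsorted(ps, neg, side="left")
    right = np.searchsorted(ps, neg, side="right")
    v01 = 1.0 - (left + right) / (2.0 * pos.size)
    return v10, v01


def _var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if x.size > 1 else 0.0


def auc(scores: Sequence[float], outcomes: Sequence) -> AUCResult:
    """AUC via the Mann-Whitney statistic with DeLong SE and 95% CI."""
    pos, neg = _split(scores, outcomes)
    v10, v01 = _placements(pos, neg)
    a = float(v10.mean())
    se = float(np.sqrt(_var(v10) / pos.size + _var(v01) / neg.size))
    z = norm.ppf(0.975)
    ci = (max(0.0, a - z * se), min(1.0, a + z * se))
    return AUCResult(auc=a, se=se, ci95=ci, n_pos=int(pos.size), n_neg=int(neg.size))


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence,
) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUCs measured on the same records.

    Returns (auc_a, auc_b, z, two-sided P).  Identical placements (e.g.
    scores_b a monotone transform of scores_a) give z = 0, P = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must be aligned")
    y = np.asarray(outcomes, dtype=float)
    pos_a, neg_a = _split(sa, y)
    pos_b, neg_b = _split(sb, y)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return auc_a, auc_b, float(z), float(2.0 * norm.sf(abs(z)))


def delong_unpaired_test(
    scores_a: Sequence[float],
    outcomes_a: Sequence,
    scores_b: Sequence[float],
    outcomes_b: Sequence,
) -> tuple[float, float]:
    """DeLong z-test for AUCs from two independent samples; returns (z, P)."""
    ra = auc(scores_a, outcomes_a)
    rb = auc(scores_b, outcomes_b)
    var = ra.se ** 2 + rb.se ** 2
    if var <= 0:
        return (0.0, 1.0) if ra.auc == rb.auc else (float("inf"), 0.0)
    z = (ra.auc - rb.auc) / np.sqrt(var)
    return float(z), float(2.0 * norm.sf(abs(z)))


def plot_roc(curves: dict[str, ROCCurve], path, title: Optional[str] = None) -> None:
    """Export a simple ROC plot (cosmetic helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=name, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
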