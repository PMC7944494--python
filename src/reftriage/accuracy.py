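"""Diagnostic-accuracy summaries and the univariable comparison tests.

Accuracy of a dichotomous triage decision (urgent vs routine) against the
cancer outcome: sensitivity, specificity, PPV and the false omission rate
(FOR — the share of routine referrals that turn out to have cancer,
1 − NPV), each with a 95% confidence interval (Clopper-Pearson exact by
default, Wilson optionally).  Group comparisons use the Pearson χ² test
without continuity correction and the Mann-Whitney U test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "AccuracySummary",
    "Estimate",
    "confusion_counts",
    "accuracy_summary",
    "proportion_ci",
    "compare_proportions",
    "mann_whitney",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts of a binary decision against a binary outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            raise ValueError("empty confusion table")
        return {"tp": self.tp / t, "fp": self.fp / t, "fn": self.fn / t, "tn": self.tn / t}


class Estimate(NamedTuple):
    """Point estimate with a two-sided 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AccuracySummary:
    """Accuracy parameters of a triage rule; undefined fields are None."""

    sensitivity: Optional[Estimate]
    specificity: Optional[Estimate]
    ppv: Optional[Estimate]
    for_rate: Optional[Estimate]
    prevalence: float


def confusion_counts(decisions: Sequence, outcomes: Sequence) -> ConfusionCounts:
    """Cross-tabulate a binary decision vector against binary outcomes."""
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if d.shape != y.shape:
        raise ValueError(f"length mismatch: {d.shape} vs {y.shape}")
    if d.size == 0:
        raise ValueError("empty input")
    for name, v in (("decisions", d), ("outcomes", y)):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be 0/1")
    return ConfusionCounts(
        tp=int(((d == 1) & (y == 1)).sum()),
        fp=int(((d == 1) & (y == 0)).sum()),
        fn=int(((d == 0) & (y == 1)).sum()),
        tn=int(((d == 0) & (y == 0)).sum()),
    )


def proportion_ci(x: int, n: int, method: str = "clopper-pearson",
                  level: float = 0.95) -> tuple[float, float]:
    """Two-sided binomial CI for x successes out of n."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lo, hi
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        p = x / n
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown CI method {method!r}")


def _estimate(x: int, n: int, method: str) -> Optional[Estimate]:
    if n == 0:
        return None
    lo, hi = proportion_ci(x, n, method=method)
    return Estimate(x / n, lo, hi)


def accuracy_summary(counts: ConfusionCounts,
                     ci_method: str = "clopper-pearson") -> AccuracySummary:
    """Sensitivity, specificity, PPV and FOR with 95% CIs.

    A zero denominator leaves the corresponding field undefined (None)
    rather than raising — mirrors the "n.a." convention of clinical
    accuracy tables.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    return AccuracySummary(
        sensitivity=_estimate(counts.tp, counts.tp + counts.fn, ci_method),
        specificity=_estimate(counts.tn, counts.fp + counts.tn, ci_method),
        ppv=_estimate(counts.tp, counts.tp + counts.fp, ci_method),
        for_rate=_estimate(counts.fn, counts.fn + counts.tn, ci_method),
        prevalence=(counts.tp + counts.fn) / counts.total,
    )


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Pearson χ² (1 df, no continuity correction) on a 2×2 table."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n > 0 in each sample")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); P undefined")
        return float("nan")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a, with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


_EXACT_TOTAL = 20  # full enumeration is feasible up to C(20, 10) label splits


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample a, two-sided P).

    Small samples (combined n <= 20) use exact enumeration of all group
    labelings (valid under ties); larger samples use the tie-corrected
    normal approximation without continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n1, n2 = len(a), len(b)
    if n1 + n2 <= _EXACT_TOTAL:
        res = stats.permutation_test(
            (a, b),
            statistic=lambda x, y: _u_statistic(np.asarray(x), np.asarray(y)),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return u_obs, float(min(res.pvalue, 1.0))
    pooled = np.concatenate([a, b])
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(var)
    return u_obs, float(2.0 * stats.norm.sf(abs(z)))
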