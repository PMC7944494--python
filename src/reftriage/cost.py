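"""Cost-weighted optimal referral threshold (ORT) engine.

The net cost per referral of a dichotomous triage rule is the
cost-weighted average of the four outcome proportions,

    cost = TPc*TPp + TNc*TNp + FPc*FPp + FNc*FNp,

where the unit costs (FNc, FPc, TPc, TNc) encode a cost-benefit
assumption (benefits as negative costs; ratios anchored at FPc = 1 and
TNc = -1, so "100:1 / -10:-1" means FNc = 100, TPc = -10).  The ORT of a
score is the cut-off minimizing this cost over every dichotomization
"positive iff score >= t" plus the two degenerate policies (refer all
urgently / all routinely); ties break toward the fewer urgent referrals.
DeltaCost compares two models as a percentage of the reference model's
absolute cost, so an improvement is always negative.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .accuracy import AccuracySummary, ConfusionCounts, accuracy_summary
from .cohort import Cohort
from .roc import SingleClassError

__all__ = [
    "CostAssumption",
    "ORTResult",
    "DEFAULT_ASSUMPTIONS",
    "average_cost",
    "delta_cost",
    "find_ort",
    "metz_slope",
    "comparison_table",
]


@dataclass(frozen=True)
class CostAssumption:
    """Unit costs of the four triage outcomes; benefits are negative."""

    fn_cost: float
    fp_cost: float
    tp_cost: float
    tn_cost: float
    label: str = ""

    def __post_init__(self):
        if not self.label:
            object.__setattr__(self, "label", self.make_label())

    def make_label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return (f"{fmt(self.fn_cost)}:{fmt(self.fp_cost)}/"
                f"{fmt(self.tp_cost)}:{fmt(self.tn_cost)}")

    @classmethod
    def parse_label(cls, label: str) -> "CostAssumption":
        """Parse "FNc:FPc/TPc:TNc", e.g. "100:1/-10:-1"."""
        m = re.fullmatch(
            r"\s*(-?[\d.]+)\s*:\s*(-?[\d.]+)\s*/\s*(-?[\d.]+)\s*:\s*(-?[\d.]+)\s*",
            label,
        )
        if not m:
            raise ValueError(f"cannot parse cost label {label!r}")
        fn, fp, tp, tn = (float(g) for g in m.groups())
        return cls(fn_cost=fn, fp_cost=fp, tp_cost=tp, tn_cost=tn)

    @classmethod
    def from_ratios(cls, fn_ratio: float, tp_ratio: float) -> "CostAssumption":
        """Anchored assumption: FPc = 1, TNc = -1, FNc = ratio, TPc = ratio."""
        return cls(fn_cost=float(fn_ratio), fp_cost=1.0,
                   tp_cost=float(tp_ratio), tn_cost=-1.0)

    def scaled(self, k: float) -> "CostAssumption":
        return replace(self, fn_cost=self.fn_cost * k, fp_cost=self.fp_cost * k,
                       tp_cost=self.tp_cost * k, tn_cost=self.tn_cost * k,
                       label=f"{self.label}*{k:g}")


#: the eight-assumption grid: FNc:FPc in {150, 100, 50, 1} x TPc:TNc in {-1, -10}
DEFAULT_ASSUMPTIONS = tuple(
    CostAssumption.from_ratios(fn, tp)
    for fn in (150.0, 100.0, 50.0, 1.0)
    for tp in (-1.0, -10.0)
)


def average_cost(counts: ConfusionCounts, assumption: CostAssumption) -> float:
    """Net cost per referral: cost-weighted sum of outcome proportions."""
    p = counts.proportions()
    return (assumption.tp_cost * p["tp"] + assumption.tn_cost * p["tn"]
            + assumption.fp_cost * p["fp"] + assumption.fn_cost * p["fn"])


def delta_cost(cost_model: float, cost_reference: float) -> float:
    """Percentage cost change vs the reference, denominated in |reference|."""
    if cost_reference == 0:
        warnings.warn("reference cost is zero; DeltaCost undefined")
        return float("nan")
    return (cost_model - cost_reference) / abs(cost_reference) * 100.0


@dataclass
class ORTResult:
    """Cost-minimizing dichotomization of a score."""

    ort: float  # threshold on the score scale; +inf for the all-negative policy
    policy: str  # "all_positive" | "all_negative" | "cutoff"
    counts: ConfusionCounts
    accuracy: AccuracySummary
    urgent_fraction: float
    net_cost: float
    delta_cost_pct: Optional[float] = None


_TIE_EPS = 1e-12


def find_ort(
    scores: Sequence[float],
    outcomes: Sequence,
    assumption: CostAssumption,
) -> ORTResult:
    """Exhaustive cost minimization over every dichotomization of a score.

    Candidate cut-offs are the unique observed score values (rule:
    positive iff score >= t; the smallest value is the all-positive
    policy) plus the all-negative policy.  At equal minimal cost the
    candidate with the fewest urgent referrals wins.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and outcomes must be aligned and non-empty")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    n_pos = int(y.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both outcome classes must be present")

    order = np.argsort(-s, kind="mergesort")
    ss, yy = s[order], y[order]
    last = np.nonzero(np.append(ss[1:] != ss[:-1], True))[0]
    tp = np.cumsum(yy)[last]
    fp = (last + 1) - tp
    # prepend the all-negative policy (threshold above every score)
    thresholds = np.concatenate([[np.inf], ss[last]])
    tp = np.concatenate([[0.0], tp])
    fp = np.concatenate([[0.0], fp])
    fn = n_pos - tp
    tn = n_neg - fp
    n = s.size
    costs = (assumption.tp_cost * tp + assumption.tn_cost * tn
             + assumption.fp_cost * fp + assumption.fn_cost * fn) / n

    cmin = costs.min()
    tied = np.nonzero(costs <= cmin + _TIE_EPS)[0]
    best = tied[np.argmin((tp + fp)[tied])]

    counts = ConfusionCounts(tp=int(tp[best]), fp=int(fp[best]),
                             fn=int(fn[best]), tn=int(tn[best]))
    urgent = counts.tp + counts.fp
    if urgent == 0:
        policy = "all_negative"
    elif urgent == n:
        policy = "all_positive"
    else:
        policy = "cutoff"
    return ORTResult(
        ort=float(thresholds[best]),
        policy=policy,
        counts=counts,
        accuracy=accuracy_summary(counts),
        urgent_fraction=urgent / n,
        net_cost=float(costs[best]),
    )


def metz_slope(assumption: CostAssumption, prevalence: float) -> float:
    """ROC slope at the cost-optimal operating point.

    ((1-prev)/prev) * ((FPc - TNc)/(FNc - TPc)); the classical
    decision-theoretic identity linking the cost assumption to the optimal
    cut-point of a smooth ROC curve.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly in (0, 1)")
    denom = assumption.fn_cost - assumption.tp_cost
    if denom == 0:
        raise ValueError("FNc equals TPc: slope undefined")
    return ((1.0 - prevalence) / prevalence
            * (assumption.fp_cost - assumption.tn_cost) / denom)


ScoreProvider = Union[Callable[[Cohort], np.ndarray], Sequence[float], np.ndarray]


def _resolve_scores(provider: ScoreProvider, cohort: Cohort, n: int) -> np.ndarray:
    s = np.asarray(provider(cohort) if callable(provider) else provider, dtype=float)
    if s.shape != (n,):
        raise ValueError(f"score provider returned shape {s.shape}, expected ({n},)")
    return s


def comparison_table(
    cohort: Cohort,
    models: Mapping[str, ScoreProvider],
    assumptions: Sequence[CostAssumption] = DEFAULT_ASSUMPTIONS,
    reference_model: Optional[str] = None,
    outcome: str = "cancer",
) -> pd.DataFrame:
    """Per (assumption x model) block of the model-comparison report.

    Each row: ORT, urgent fraction, accuracy parameters, AUC of the
    dichotomized rule ((sensitivity + specificity)/2), net cost, and
    DeltaCost vs the reference model and vs the previous model in the
    listed order.  Models with missing scores are reduced to their
    complete cases (the reduction count is reported in ``n_used``).
    """
    from .roc import auc as _auc

    model_names = list(models)
    if reference_model is None:
        reference_model = model_names[0]
    if reference_model not in models:
        raise ValueError(f"reference model {reference_model!r} not among models")

    frame = cohort.frame
    y_all = frame[outcome].to_numpy(dtype=float)
    n = len(frame)
    scores = {name: _resolve_scores(p, cohort, n) for name, p in models.items()}

    rows = []
    for assumption in assumptions:
        block: dict[str, ORTResult] = {}
        for name in model_names:
            s = scores[name]
            mask = np.isfinite(s) & ~np.isnan(y_all)
            block[name] = find_ort(s[mask], y_all[mask], assumption)
            block[name]._n_used = int(mask.sum())  # type: ignore[attr-defined]
        ref_cost = block[reference_model].net_cost
        prev_name = None
        for name in model_names:
            res = block[name]
            mask = np.isfinite(scores[name]) & ~np.isnan(y_all)
            decisions = (scores[name][mask] >= res.ort).astype(float)
            dec_auc = _auc(decisions, y_all[mask])
            res.delta_cost_pct = 0.0 if name == reference_model \
                else delta_cost(res.net_cost, ref_cost)
            d_prev = (None if prev_name is None
                      else delta_cost(res.net_cost, block[prev_name].net_cost))
            acc = res.accuracy
            rows.append({
                "assumption": assumption.label,
                "model": name,
                "n_used": res._n_used,  # type: ignore[attr-defined]
                "ort": res.ort,
                "policy": res.policy,
                "urgent": res.counts.tp + res.counts.fp,
                "urgent_fraction": res.urgent_fraction,
                "sensitivity": None if acc.sensitivity is None else acc.sensitivity.value,
                "specificity": None if acc.specificity is None else acc.specificity.value,
                "ppv": None if acc.ppv is None else acc.ppv.value,
                "for_rate": None if acc.for_rate is None else acc.for_rate.value,
                "auc": dec_auc.auc,
                "tp": res.counts.tp, "fp": res.counts.fp,
                "fn": res.counts.fn, "tn": res.counts.tn,
                "net_cost": res.net_cost,
                "delta_cost_vs_reference": res.delta_cost_pct,
                "delta_cost_vs_previous": d_prev,
            })
            prev_name = name
    return pd.DataFrame(rows)
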