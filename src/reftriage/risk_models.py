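"""Logistic risk modelling for referral triage.

Builds the multivariable risk model the pipeline compares against the
binary urgent-referral route: a univariable screen (retain candidates with
P < 0.250), maximum-likelihood logistic fitting (statsmodels GLM/IRLS)
with Wald inference, backward elimination down to P < 0.050, prediction,
and the usual fit diagnostics (Nagelkerke pseudo-R², Hosmer-Lemeshow).

Complete-case handling mirrors a registry analysis: each fit drops rows
with a missing value in any used column; ``stepwise_exclude`` fixes the
complete-case set on the union of its starting predictors so the
likelihoods along the elimination path are comparable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .cohort import Cohort, ReferralRecord, FAMILY_HISTORY_LEVELS

__all__ = [
    "LogisticFit",
    "ScreenResult",
    "SeparationError",
    "SingularDesignError",
    "fit_logistic",
    "univariable_screen",
    "stepwise_exclude",
    "predict_probability",
    "nagelkerke_r2",
    "hosmer_lemeshow",
]

SEPARATION_COEF_BOUND = 15.0  # |log-odds| beyond this flags quasi-separation

#: multi-level terms expand to k-1 indicator columns
TERM_COLUMNS = {
    "family_history": ["family_history_second_degree", "family_history_first_degree"],
    "route": ["route_urgent"],
}


class SeparationError(RuntimeError):
    """(Quasi-)complete separation: a coefficient diverges."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


def _as_frame(data: Union[Cohort, pd.DataFrame]) -> pd.DataFrame:
    return data.frame if isinstance(data, Cohort) else data


def term_columns(term: str) -> list[str]:
    return TERM_COLUMNS.get(term, [term])


def build_design(frame: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Expand model terms to numeric design columns (no intercept)."""
    cols: dict[str, np.ndarray] = {}
    for t in terms:
        if t == "family_history":
            fh = frame["family_history"]
            miss = fh.isna().to_numpy()
            for level in FAMILY_HISTORY_LEVELS[1:]:
                ind = (fh == level).to_numpy(dtype=float)
                ind[miss] = np.nan
                cols[f"family_history_{level}"] = ind
        elif t == "route":
            cols["route_urgent"] = (frame["route"] == "urgent").to_numpy(dtype=float)
        else:
            cols[t] = frame[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=frame.index)


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, Wald inference, diagnostics."""

    terms: list[str]
    columns: list[str]
    params: dict[str, float]  # includes "intercept"
    bse: dict[str, float]
    n_used: float
    loglik: float
    loglik_null: float
    converged: bool
    trace: list = field(default_factory=list)  # (dropped term, P) pairs

    def coefficients(self) -> dict[str, float]:
        return dict(self.params)

    def pvalues(self) -> dict[str, float]:
        out = {}
        for c in self.columns:
            se = self.bse[c]
            z = self.params[c] / se if se > 0 else np.inf
            out[c] = 2.0 * norm.sf(abs(z))
        return out

    def odds_ratios(self, level: float = 0.95) -> dict[str, tuple[float, float, float]]:
        """Per design column: (OR, Wald CI low, Wald CI high)."""
        zq = norm.ppf(0.5 + level / 2.0)
        out = {}
        for c in self.columns:
            b, se = self.params[c], self.bse[c]
            out[c] = (np.exp(b), np.exp(b - zq * se), np.exp(b + zq * se))
        return out

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "columns": self.columns,
            "coefficients": self.params,
            "standard_errors": self.bse,
            "odds_ratios": {k: list(v) for k, v in self.odds_ratios().items()},
            "p_values": self.pvalues(),
            "n_used": self.n_used,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "converged": self.converged,
            "trace": [list(t) for t in self.trace],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass
class ScreenResult:
    """Univariable screen outcome: per-candidate P and the retained set."""

    pvalues: dict[str, float]
    included: set[str]
    alpha_in: float


def _null_loglik(y: np.ndarray, w: Optional[np.ndarray]) -> float:
    if w is None:
        w = np.ones_like(y)
    tot = w.sum()
    p = float((w * y).sum() / tot)
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(tot * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def _fit_glm(y, X, w):
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-10)


def fit_logistic(
    data: Union[Cohort, pd.DataFrame],
    predictors: Sequence[str],
    outcome: str = "cancer",
    weights: Optional[Sequence[float]] = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``outcome`` on ``predictors``.

    ``weights`` are frequency weights for grouped data.  Complete cases
    only; requires at least 10 observations per design column.  Raises
    :class:`SeparationError` when a coefficient diverges and
    :class:`SingularDesignError` on a rank-deficient design.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("predictors must be non-empty")
    frame = _as_frame(data)
    X = build_design(frame, predictors)
    y = frame[outcome].to_numpy(dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)

    mask = ~np.isnan(y)
    mask &= X.notna().all(axis=1).to_numpy()
    if w is not None:
        mask &= ~np.isnan(w)
    Xm = X.loc[mask]
    ym = y[mask]
    wm = None if w is None else w[mask]
    n_used = float(len(ym) if wm is None else wm.sum())

    if n_used < 10 * len(X.columns):
        raise ValueError(
            f"{n_used:.0f} complete cases for {len(X.columns)} design columns; "
            "need at least 10 per column"
        )

    Xc = sm.add_constant(Xm, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")

    res = _fit_glm(ym, Xc, wm)
    params = np.asarray(res.params, dtype=float)
    names = ["intercept"] + list(X.columns)
    big = [n for n, b in zip(names[1:], params[1:]) if abs(b) > SEPARATION_COEF_BOUND]
    if big:
        raise SeparationError(f"separation suspected for predictor(s) {big}")

    return LogisticFit(
        terms=predictors,
        columns=list(X.columns),
        params={n: float(b) for n, b in zip(names, params)},
        bse={n: float(s) for n, s in zip(names, np.asarray(res.bse, dtype=float))},
        n_used=n_used,
        loglik=float(res.llf),
        loglik_null=_null_loglik(ym, wm),
        converged=bool(res.converged),
    )


def _intercept_only_fit(frame: pd.DataFrame, outcome: str) -> LogisticFit:
    y = frame[outcome].to_numpy(dtype=float)
    y = y[~np.isnan(y)]
    p = float(y.mean())
    ll = _null_loglik(y, None)
    b0 = np.inf if p >= 1.0 else (-np.inf if p <= 0.0 else float(np.log(p / (1 - p))))
    se = np.sqrt(1.0 / (len(y) * p * (1 - p))) if 0 < p < 1 else np.nan
    return LogisticFit(
        terms=[], columns=[], params={"intercept": b0}, bse={"intercept": float(se)},
        n_used=float(len(y)), loglik=ll, loglik_null=ll, converged=True,
    )


def _term_pvalue(
    frame: pd.DataFrame,
    fit: LogisticFit,
    term: str,
    outcome: str,
) -> float:
    """P value for a whole term: Wald for a single column, LR for multi-level."""
    cols = term_columns(term)
    if len(cols) == 1:
        return fit.pvalues()[cols[0]]
    reduced_terms = [t for t in fit.terms if t != term]
    if reduced_terms:
        reduced = fit_logistic(frame, reduced_terms, outcome=outcome)
        ll0 = reduced.loglik
    else:
        ll0 = fit.loglik_null
    stat = 2.0 * (fit.loglik - ll0)
    return float(chi2.sf(max(stat, 0.0), df=len(cols)))


def univariable_screen(
    data: Union[Cohort, pd.DataFrame],
    candidates: Sequence[str],
    alpha_in: float = 0.250,
    outcome: str = "cancer",
) -> ScreenResult:
    """Test each candidate alone; retain those with P < ``alpha_in``.

    Single-column candidates use the Wald test on their coefficient;
    multi-level categorical candidates use a joint likelihood-ratio test.
    Candidates with a single observed level are excluded with a warning.
    """
    if not (0.0 < alpha_in <= 1.0):
        raise ValueError("alpha_in must lie in (0, 1]")
    frame = _as_frame(data)
    pvalues: dict[str, float] = {}
    included: set[str] = set()
    for cand in candidates:
        X = build_design(frame, [cand])
        ok = X.notna().all(axis=1).to_numpy() & frame[outcome].notna().to_numpy()
        degenerate = any(X.loc[ok, c].nunique() <= 1 for c in X.columns)
        if degenerate or ok.sum() == 0:
            warnings.warn(f"candidate {cand!r} has a single observed level; excluded")
            pvalues[cand] = np.nan
            continue
        fit = fit_logistic(frame, [cand], outcome=outcome)
        if len(X.columns) == 1:
            p = fit.pvalues()[X.columns[0]]
        else:
            stat = 2.0 * (fit.loglik - fit.loglik_null)
            p = float(chi2.sf(max(stat, 0.0), df=len(X.columns)))
        pvalues[cand] = float(p)
        if p < alpha_in:
            included.add(cand)
    return ScreenResult(pvalues=pvalues, included=included, alpha_in=alpha_in)


def stepwise_exclude(
    data: Union[Cohort, pd.DataFrame],
    predictors: Sequence[str],
    alpha_stay: float = 0.050,
    outcome: str = "cancer",
) -> LogisticFit:
    """Backward elimination: drop the worst predictor with P >= ``alpha_stay``.

    Repeatedly refits, removing the term with the largest P value at or
    above the threshold, until all remaining terms have P < ``alpha_stay``.
    The complete-case set is fixed on the union of the starting predictors.
    Returns the final fit with the elimination trace attached; an empty
    final model degrades to an intercept-only fit with a warning.
    """
    current = list(predictors)
    frame = _as_frame(data)
    used_cols = [c for t in current for c in term_columns(t)]
    X = build_design(frame, current) if current else pd.DataFrame(index=frame.index)
    keep = frame[outcome].notna().to_numpy()
    if used_cols:
        keep &= X.notna().all(axis=1).to_numpy()
    frame = frame.loc[keep]

    trace: list[tuple[str, float]] = []
    while current:
        fit = fit_logistic(frame, current, outcome=outcome)
        term_p = {t: _term_pvalue(frame, fit, t, outcome) for t in current}
        worst = max(term_p, key=lambda t: term_p[t])
        if term_p[worst] >= alpha_stay:
            trace.append((worst, float(term_p[worst])))
            current.remove(worst)
        else:
            fit.trace = trace
            return fit
    warnings.warn("all predictors eliminated; returning intercept-only fit")
    fit = _intercept_only_fit(frame, outcome)
    fit.trace = trace
    return fit


def predict_probability(
    fit: LogisticFit,
    data: Union[ReferralRecord, Mapping, pd.DataFrame, Cohort],
):
    """Inverse-logit of the linear predictor for one record or a frame.

    Raises on a missing value among the fit's predictors.  Returns a float
    for a single record, a numpy array for tabular input.
    """
    single = False
    if isinstance(data, ReferralRecord):
        data = pd.DataFrame([{c: getattr(data, c) for c in data.__dataclass_fields__}])
        single = True
    elif isinstance(data, Mapping):
        data = pd.DataFrame([dict(data)])
        single = True
    frame = _as_frame(data)
    X = build_design(frame, fit.terms) if fit.terms else pd.DataFrame(index=frame.index)
    if fit.terms and X.isna().any().any():
        bad = [c for c in X.columns if X[c].isna().any()]
        raise ValueError(f"missing predictor value(s) in {bad}")
    eta = np.full(len(frame), fit.params["intercept"], dtype=float)
    for c in fit.columns:
        eta += fit.params[c] * X[c].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return float(prob[0]) if single else prob


def score_frame(fit: LogisticFit, data: Union[pd.DataFrame, Cohort]) -> np.ndarray:
    """Predicted probabilities with NaN where a predictor is missing."""
    frame = _as_frame(data)
    X = build_design(frame, fit.terms) if fit.terms else pd.DataFrame(index=frame.index)
    ok = X.notna().all(axis=1).to_numpy() if fit.terms else np.ones(len(frame), bool)
    out = np.full(len(frame), np.nan)
    if ok.any():
        out[ok] = predict_probability(fit, frame.loc[ok])
    return out


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell R² scaled by its attainable maximum."""
    n = fit.n_used
    if n <= 0:
        raise ValueError("fit has no observations")
    cox_snell = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    max_cs = 1.0 - np.exp(2.0 * fit.loglik_null / n)
    if max_cs <= 0:
        raise ValueError("degenerate outcome: Nagelkerke maximum is zero")
    return float(cox_snell / max_cs)


def hosmer_lemeshow(
    fit: LogisticFit,
    data: Union[Cohort, pd.DataFrame],
    groups: int = 10,
) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit test on risk-decile groups.

    Groups are equal-count quantile bins of predicted risk with ties kept
    together; groups with zero expected events (or non-events) are merged
    with their neighbour with a warning.  Returns (chi², P) with
    ``groups - 2`` degrees of freedom (of the groups actually used).
    """
    if groups < 2:
        raise ValueError("need at least 2 groups")
    frame = _as_frame(data)
    X = build_design(frame, fit.terms) if fit.terms else pd.DataFrame(index=frame.index)
    ok = frame["cancer"].notna().to_numpy()
    if fit.terms:
        ok &= X.notna().all(axis=1).to_numpy()
    frame = frame.loc[ok]
    if len(frame) < groups:
        raise ValueError("fewer observations than groups")
    p = predict_probability(fit, frame)
    y = frame["cancer"].to_numpy(dtype=float)

    bins = pd.qcut(p, groups, labels=False, duplicates="drop")
    table = pd.DataFrame({"y": y, "p": p, "g": bins}).groupby("g").agg(
        n=("y", "size"), obs=("y", "sum"), exp=("p", "sum")
    ).sort_index()

    # merge groups whose expected events or non-events are zero
    rows = table.to_dict("records")
    merged = []
    for row in rows:
        if merged and (row["exp"] <= 0 or (row["n"] - row["exp"]) <= 0):
            warnings.warn("Hosmer-Lemeshow group with zero expected count merged")
            for k in ("n", "obs", "exp"):
                merged[-1][k] += row[k]
        else:
            merged.append(dict(row))
    # a leading degenerate group merges forward
    while len(merged) > 1 and (merged[0]["exp"] <= 0 or (merged[0]["n"] - merged[0]["exp"]) <= 0):
        warnings.warn("Hosmer-Lemeshow group with zero expected count merged")
        for k in ("n", "obs", "exp"):
            merged[1][k] += merged[0][k]
        merged = merged[1:]

    g = len(merged)
    if g < 2:
        raise ValueError("too few usable groups for the test")
    stat = 0.0
    for row in merged:
        e1, o1 = row["exp"], row["obs"]
        e0, o0 = row["n"] - e1, row["n"] - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    pval = float(chi2.sf(stat, df=max(g - 2, 1)))
    return float(stat), pval
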