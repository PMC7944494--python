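"""Synthetic referral-cohort generator.

Emulates the statistical structure of a consecutive symptomatic breast
referral cohort: age drawn from a log-normal matched to the published
quartiles (36 / 46 / 57 years, clipped to 1-100), binary covariates at
their marginal frequencies, menopause logistic in age, the cancer outcome
generated by a logistic model with per-predictor odds ratios (defaults:
age 1.07 per year, TOP-T 4.85, TOP-O 1.73, TOP-P 0.46, gravidity 0.72)
whose intercept is calibrated so the population prevalence equals the
target (default 6.9%), and the urgent/choose-and-book route drawn
conditionally on the outcome with fixed sensitivity 89.9% and specificity
40.5%.

Determinism: a given ``(config, seed)`` yields byte-identical cohorts; the
random draw order per stage is fixed (age, menopause, TOP-T, TOP-O, TOP-P,
gravidity, breastfeeding, previous cancer, family history, HRT, outcome,
route). Intercept calibration itself uses no randomness (quadrature).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, CSV_COLUMNS, MISSABLE_FIELDS, CohortError

__all__ = [
    "GeneratorConfig",
    "calibrate_intercept",
    "generate_cohort",
    "inject_missingness",
    "outcome_probability",
]

_REFERENCE_TOTAL = 7915  # published cohort size used for default missingness rates


def _default_marginals() -> dict[str, float]:
    return {
        "top_t": 0.686,
        "top_o": 0.169,
        "top_p": 0.333,
        "gravidity": 0.826,
        "previous_bc": 0.081,
        "menopause": 0.393,
        "breastfeeding": 0.496,
        "hrt": 0.087,
    }


def _default_outcome_or() -> dict[str, float]:
    return {"age": 1.07, "top_t": 4.85, "top_o": 1.73, "top_p": 0.46, "gravidity": 0.72}


def _default_missingness() -> dict[str, float]:
    return {
        "gravidity": 50 / _REFERENCE_TOTAL,
        "breastfeeding": 85 / _REFERENCE_TOTAL,
        "family_history": 88 / _REFERENCE_TOTAL,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n: int = _REFERENCE_TOTAL
    seed: int = 0
    age_quartiles: tuple[float, float, float] = (36.0, 46.0, 57.0)
    age_range: tuple[float, float] = (1.0, 100.0)
    marginal_prevalences: dict[str, float] = field(default_factory=_default_marginals)
    family_history_probs: tuple[float, float, float] = (0.672, 0.169, 0.159)
    outcome_or: dict[str, float] = field(default_factory=_default_outcome_or)
    target_prevalence: float = 0.069
    route_sensitivity: float = 0.899
    route_specificity: float = 0.405
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    menopause_scale: float = 4.0  # years; steepness of the menopause-age logistic

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        q1, q2, q3 = self.age_quartiles
        lo, hi = self.age_range
        if not (lo <= q1 <= q2 <= q3 <= hi):
            raise ValueError("age quartiles must be ordered and inside age_range")
        if lo <= 0:
            raise ValueError("age_range lower bound must be positive (log-normal)")
        for name, p in {**self.marginal_prevalences,
                        "target_prevalence": self.target_prevalence,
                        "route_sensitivity": self.route_sensitivity,
                        "route_specificity": self.route_specificity,
                        **self.missingness_rates}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if abs(sum(self.family_history_probs) - 1.0) > 1e-9:
            raise ValueError("family_history_probs must sum to 1")
        for k, v in self.outcome_or.items():
            if v <= 0:
                raise ValueError(f"odds ratio for {k} must be positive")
            if k != "age" and k not in self.marginal_prevalences:
                raise ValueError(f"outcome predictor {k!r} has no marginal prevalence")
        bad = set(self.missingness_rates) - MISSABLE_FIELDS
        if bad:
            raise ValueError(f"missingness rate for non-missable field(s) {sorted(bad)}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Age distribution and calibration quadrature
# --------------------------------------------------------------------------
_Z_QUARTILES = norm.ppf([0.25, 0.5, 0.75])


def _lognormal_params(quartiles) -> tuple[float, float]:
    """Least-squares fit of (mu, sigma) on the log scale to three quantiles."""
    logq = np.log(np.asarray(quartiles, dtype=float))
    z = _Z_QUARTILES
    sigma = float(z @ logq / (z @ z))
    mu = float(logq.mean())
    if sigma <= 0:
        raise ValueError("age quartiles imply non-positive spread")
    return mu, sigma


def _age_grid(config: GeneratorConfig, m: int = 8001) -> np.ndarray:
    """Midpoint-quantile quadrature nodes of the clipped age distribution."""
    mu, sigma = _lognormal_params(config.age_quartiles)
    p = (np.arange(m) + 0.5) / m
    ages = np.exp(mu + sigma * norm.ppf(p))
    return np.clip(ages, config.age_range[0], config.age_range[1])


def _menopause_location(config: GeneratorConfig) -> float:
    """Age at 50% menopause probability, calibrated to the marginal."""
    target = config.marginal_prevalences["menopause"]
    ages = _age_grid(config)
    scale = config.menopause_scale

    def gap(c):
        return expit((ages - c) / scale).mean() - target

    return brentq(gap, -200.0, 400.0, xtol=1e-8)


def _covariate_digest(config: GeneratorConfig) -> str:
    payload = json.dumps(
        [config.age_quartiles, config.age_range,
         sorted(config.marginal_prevalences.items()),
         sorted(config.outcome_or.items()), config.target_prevalence],
        sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()


_INTERCEPT_CACHE: dict[str, float] = {}


def calibrate_intercept(config: GeneratorConfig) -> float:
    """Intercept (log-odds) making population prevalence equal the target.

    The population average of the logistic outcome probability is computed
    by deterministic quadrature: a midpoint-quantile grid over the clipped
    log-normal age distribution crossed with exact enumeration of the
    binary-predictor combinations (predictors are generated independently,
    so combination weights are products of marginals).  The root in the
    intercept is found by Brent bracketing; the result is cached per
    covariate-model digest and is deterministic.
    """
    config.validate()
    key = _covariate_digest(config)
    if key in _INTERCEPT_CACHE:
        return _INTERCEPT_CACHE[key]

    betas = {k: math.log(v) for k, v in config.outcome_or.items()}
    ages = _age_grid(config)
    base = betas.get("age", 0.0) * ages
    binary = sorted(k for k in betas if k != "age")
    combos = []
    for bits in itertools.product((0, 1), repeat=len(binary)):
        w = 1.0
        off = 0.0
        for k, b in zip(binary, bits):
            p = config.marginal_prevalences[k]
            w *= p if b else 1.0 - p
            off += betas[k] * b
        if w > 0:
            combos.append((w, off))

    def prevalence(b0: float) -> float:
        return sum(w * expit(b0 + base + off).mean() for w, off in combos)

    target = config.target_prevalence
    lo, hi = -50.0, 30.0
    f_lo, f_hi = prevalence(lo) - target, prevalence(hi) - target
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "intercept root not bracketed: "
            f"prevalence({lo})={f_lo + target:.6g}, prevalence({hi})={f_hi + target:.6g}"
        )
    b0 = brentq(lambda b: prevalence(b) - target, lo, hi, xtol=1e-10)
    _INTERCEPT_CACHE[key] = float(b0)
    return float(b0)


def outcome_probability(
    config: GeneratorConfig,
    covariates: Mapping[str, np.ndarray],
    intercept: Optional[float] = None,
) -> np.ndarray:
    """Cancer probability under the generating logistic model."""
    if intercept is None:
        intercept = calibrate_intercept(config)
    eta = np.full_like(np.asarray(covariates["age"], dtype=float), intercept)
    for k, orr in config.outcome_or.items():
        eta = eta + math.log(orr) * np.asarray(covariates[k], dtype=float)
    return expit(eta)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------
def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a complete synthetic cohort (no missingness; see
    :func:`inject_missingness` for the observed missing-data pattern)."""
    config.validate()
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    marg = config.marginal_prevalences

    mu, sigma = _lognormal_params(config.age_quartiles)
    # inverse-CDF draws keep the per-stage consumption order stable
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        age = np.exp(mu + sigma * norm.ppf(u))
    age = np.clip(age, config.age_range[0], config.age_range[1])

    meno_loc = _menopause_location(config)
    menopause = (rng.random(n) < expit((age - meno_loc) / config.menopause_scale)).astype(float)

    top_t = (rng.random(n) < marg["top_t"]).astype(float)
    top_o = (rng.random(n) < marg["top_o"]).astype(float)
    top_p = (rng.random(n) < marg["top_p"]).astype(float)

    gravidity = (rng.random(n) < marg["gravidity"]).astype(float)
    # breastfeeding only possible when gravid; conditional rate recovers the marginal
    if marg["gravidity"] > 0:
        p_bf_given_g = marg["breastfeeding"] / marg["gravidity"]
    else:
        p_bf_given_g = 0.0
    if p_bf_given_g > 1.0:
        raise ValueError("breastfeeding marginal exceeds gravidity marginal")
    breastfeeding = gravidity * (rng.random(n) < p_bf_given_g)

    previous_bc = (rng.random(n) < marg["previous_bc"]).astype(float)

    fh_cum = np.cumsum(config.family_history_probs)
    fh_idx = np.searchsorted(fh_cum, rng.random(n), side="right")
    fh_idx = np.minimum(fh_idx, 2)
    fh_levels = np.array(["none_other", "second_degree", "first_degree"], dtype=object)
    family_history = fh_levels[fh_idx]

    hrt = (rng.random(n) < marg["hrt"]).astype(float)

    covariates = {
        "age": age, "top_t": top_t, "top_o": top_o, "top_p": top_p,
        "gravidity": gravidity, "breastfeeding": breastfeeding,
        "previous_bc": previous_bc, "menopause": menopause, "hrt": hrt,
    }
    p_cancer = outcome_probability(config, covariates)
    cancer = (rng.random(n) < p_cancer).astype(float)

    u_route = rng.random(n)
    p_urgent = np.where(cancer == 1, config.route_sensitivity, 1.0 - config.route_specificity)
    route = np.where(u_route < p_urgent, "urgent", "cb").astype(object)

    import pandas as pd

    df = pd.DataFrame({
        "id": [f"S{i:07d}" for i in range(n)],
        "age": age,
        "route": route,
        "top_t": top_t,
        "top_o": top_o,
        "top_p": top_p,
        "gravidity": gravidity,
        "previous_bc": previous_bc,
        "menopause": menopause,
        "breastfeeding": breastfeeding.astype(float),
        "family_history": family_history,
        "hrt": hrt,
        "cancer": cancer,
    }, columns=CSV_COLUMNS)
    provenance = f"synthetic:{config.digest()}:seed={config.seed}:n={n}"
    return Cohort.from_frame(df, provenance=provenance)


def inject_missingness(
    cohort: Cohort,
    rates: Mapping[str, float],
    seed: int = 0,
) -> Cohort:
    """Set each named missable field to missing completely at random."""
    bad = set(rates) - MISSABLE_FIELDS
    if bad:
        raise CohortError(f"cannot inject missingness into non-missable field(s) {sorted(bad)}")
    for k, r in rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"missingness rate {k}={r} outside [0, 1]")
    df = cohort.frame
    rng = np.random.default_rng(seed)
    for name in sorted(rates):
        mask = rng.random(len(df)) < rates[name]
        if name == "family_history":
            df.loc[mask, name] = np.nan
        else:
            df.loc[mask, name] = np.nan
    return Cohort.from_frame(df, provenance=cohort.provenance + "+missingness")
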