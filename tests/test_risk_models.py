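"""Logistic fitting, screening, backward elimination and diagnostics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest, norm

from reftriage.synthetic import GeneratorConfig, generate_cohort
from reftriage.risk_models import (
    LogisticFit,
    SeparationError,
    SingularDesignError,
    fit_logistic,
    hosmer_lemeshow,
    nagelkerke_r2,
    predict_probability,
    stepwise_exclude,
    univariable_screen,
)


def grouped_2x2(a, b, c, d) -> tuple[pd.DataFrame, list]:
    """Grouped data: exposed cases a, exposed controls b, unexposed c/d."""
    frame = pd.DataFrame({"top_t": [1, 1, 0, 0], "cancer": [1, 0, 1, 0]})
    return frame, [a, b, c, d]


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        frame, w = grouped_2x2(30, 20, 10, 40)
        fit = fit_logistic(frame, ["top_t"], weights=w)
        assert math.exp(fit.params["top_t"]) == pytest.approx(
            30 * 40 / (20 * 10), rel=1e-8)

    def test_published_marginal_counts_cross_product(self):
        # univariable tumour-flag odds ratio from the printed marginal counts
        frame, w = grouped_2x2(476, 4951, 70, 2418)
        fit = fit_logistic(frame, ["top_t"], weights=w)
        assert math.exp(fit.params["top_t"]) == pytest.approx(
            476 * 2418 / (70 * 4951), rel=1e-8)

    def test_grouped_equals_ungrouped(self):
        frame, w = grouped_2x2(12, 25, 7, 40)
        grouped = fit_logistic(frame, ["top_t"], weights=w)
        rows = frame.loc[frame.index.repeat(w)].reset_index(drop=True)
        ungrouped = fit_logistic(rows, ["top_t"])
        for k in grouped.params:
            assert grouped.params[k] == pytest.approx(ungrouped.params[k], abs=1e-8)
        assert grouped.loglik == pytest.approx(ungrouped.loglik, abs=1e-6)

    def test_recovers_generating_or_within_ci(self):
        cohort = generate_cohort(GeneratorConfig(n=50_000, seed=12))
        fit = fit_logistic(cohort, ["age", "top_t", "top_o", "top_p", "gravidity"])
        orv, lo, hi = fit.odds_ratios()["top_t"]
        assert lo <= 4.85 <= hi

    def test_separation_detected(self):
        frame = pd.DataFrame({
            "x": np.r_[np.zeros(30), np.ones(30)],
            "cancer": np.r_[np.zeros(30), np.ones(30)],
        })
        with pytest.raises(SeparationError, match="x"):
            fit_logistic(frame, ["x"])

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.normal(size=60)})
        frame["x2"] = 2.0 * frame["x"]
        frame["cancer"] = (rng.random(60) < 0.4).astype(float)
        with pytest.raises(SingularDesignError):
            fit_logistic(frame, ["x", "x2"])

    def test_too_few_complete_cases_rejected(self):
        frame = pd.DataFrame({"x": np.arange(15.0),
                              "cancer": np.tile([0.0, 1.0], 8)[:15],
                              "z": np.ones(15)})
        with pytest.raises(ValueError, match="complete cases"):
            fit_logistic(frame, ["x", "z"])

    def test_noise_predictor_never_decreases_loglik(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "x": rng.normal(size=400),
            "noise": rng.normal(size=400),
        })
        frame["cancer"] = (rng.random(400) < 1 / (1 + np.exp(-frame["x"]))).astype(float)
        small = fit_logistic(frame, ["x"])
        big = fit_logistic(frame, ["x", "noise"])
        assert big.loglik >= small.loglik - 1e-9
        assert nagelkerke_r2(big) >= nagelkerke_r2(small) - 1e-12


class TestUnivariableScreen:
    def test_alpha_one_includes_all_testable(self):
        cohort = generate_cohort(GeneratorConfig(n=2_000, seed=3))
        cands = ["age", "top_t", "hrt", "family_history"]
        res = univariable_screen(cohort, cands, alpha_in=1.0)
        assert res.included == set(cands)

    def test_strong_predictors_pass_default_threshold(self):
        cohort = generate_cohort(GeneratorConfig(n=20_000, seed=3))
        res = univariable_screen(cohort, ["age", "top_t", "top_p"])
        assert {"age", "top_t", "top_p"} <= res.included
        assert all(res.pvalues[c] < 0.001 for c in ("age", "top_t", "top_p"))

    def test_single_level_candidate_excluded_with_warning(self):
        frame = generate_cohort(GeneratorConfig(n=500, seed=4)).frame
        frame["flat"] = 1.0
        with pytest.warns(UserWarning, match="single observed level"):
            res = univariable_screen(frame, ["age", "flat"])
        assert "flat" not in res.included
        assert np.isnan(res.pvalues["flat"])

    def test_inclusion_strictly_by_threshold(self):
        cohort = generate_cohort(GeneratorConfig(n=5_000, seed=6))
        res = univariable_screen(cohort, ["age", "hrt", "previous_bc"], alpha_in=0.25)
        for cand, p in res.pvalues.items():
            assert (cand in res.included) == (p < 0.25)


def _irls_wald_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent Newton-Raphson logistic solver (oracle for stepwise)."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(200):
        eta = Xc @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = Xc.T @ (y - p)
        hess = (Xc * W[:, None]).T @ Xc
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    cov = np.linalg.inv((Xc * (1.0 / (1.0 + np.exp(-(Xc @ beta)))
                               * (1 - 1.0 / (1.0 + np.exp(-(Xc @ beta)))))[:, None]).T @ Xc)
    z = beta / np.sqrt(np.diag(cov))
    return 2.0 * norm.sf(np.abs(z))[1:]  # drop intercept


class TestStepwiseExclude:
    @pytest.fixture()
    def toy_frame(self):
        rng = np.random.default_rng(11)
        n = 400
        frame = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
            "x4": rng.normal(size=n),
        })
        eta = -0.5 + 1.2 * frame["x1"] + 0.6 * frame["x2"]
        frame["cancer"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return frame

    def test_elimination_path_matches_independent_solver(self, toy_frame):
        preds = ["x1", "x2", "x3", "x4"]
        fit = stepwise_exclude(toy_frame, list(preds), alpha_stay=0.05)

        # replicate with the hand-rolled Newton oracle
        current = list(preds)
        trace = []
        y = toy_frame["cancer"].to_numpy()
        while current:
            ps = _irls_wald_pvalues(toy_frame[current].to_numpy(), y)
            worst = int(np.argmax(ps))
            if ps[worst] >= 0.05:
                trace.append((current[worst], ps[worst]))
                current.pop(worst)
            else:
                break
        assert fit.terms == current
        assert [t for t, _ in fit.trace] == [t for t, _ in trace]
        for (_, p_fit), (_, p_oracle) in zip(fit.trace, trace):
            assert p_fit == pytest.approx(p_oracle, abs=1e-6)

    def test_strong_predictors_survive(self):
        cohort = generate_cohort(GeneratorConfig(n=50_000, seed=17))
        fit = stepwise_exclude(cohort, ["age", "top_t", "top_o", "top_p", "gravidity"])
        assert set(fit.terms) == {"age", "top_t", "top_o", "top_p", "gravidity"}
        assert fit.trace == []

    def test_empty_model_degrades_to_intercept_only(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"noise": rng.normal(size=500)})
        frame["cancer"] = (rng.random(500) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="intercept-only"):
            fit = stepwise_exclude(frame, ["noise"])
        assert fit.terms == []
        assert fit.params["intercept"] == pytest.approx(
            math.log(frame["cancer"].mean() / (1 - frame["cancer"].mean())))


class TestPredict:
    def test_zero_model_gives_half(self):
        fit = LogisticFit(terms=["age"], columns=["age"],
                          params={"intercept": 0.0, "age": 0.0},
                          bse={"intercept": 1.0, "age": 1.0},
                          n_used=100, loglik=-1.0, loglik_null=-1.0, converged=True)
        assert predict_probability(fit, {"age": 55.0}) == pytest.approx(0.5)

    def test_intercept_only_prevalence(self):
        fit = LogisticFit(terms=[], columns=[],
                          params={"intercept": math.log(0.069 / 0.931)},
                          bse={"intercept": 1.0},
                          n_used=100, loglik=-1.0, loglik_null=-1.0, converged=True)
        assert predict_probability(fit, {"age": 1.0}) == pytest.approx(0.069)

    def test_hand_computed_linear_predictor(self):
        fit = LogisticFit(
            terms=["age", "top_t"], columns=["age", "top_t"],
            params={"intercept": -7.0, "age": math.log(1.07), "top_t": math.log(4.85)},
            bse={"intercept": 1.0, "age": 1.0, "top_t": 1.0},
            n_used=100, loglik=-1.0, loglik_null=-1.0, converged=True)
        eta = -7.0 + math.log(1.07) * 62.0 + math.log(4.85)
        assert predict_probability(fit, {"age": 62.0, "top_t": 1}) == pytest.approx(
            1 / (1 + math.exp(-eta)), abs=1e-12)

    def test_missing_predictor_errors(self):
        fit = LogisticFit(terms=["age"], columns=["age"],
                          params={"intercept": 0.0, "age": 0.1},
                          bse={"intercept": 1.0, "age": 1.0},
                          n_used=100, loglik=-1.0, loglik_null=-1.0, converged=True)
        frame = pd.DataFrame({"age": [np.nan], "cancer": [0.0]})
        with pytest.raises(ValueError, match="missing"):
            predict_probability(fit, frame)


class TestNagelkerke:
    def test_null_model_gives_zero(self):
        fit = LogisticFit(terms=[], columns=[], params={"intercept": 0.0},
                          bse={"intercept": 1.0}, n_used=50,
                          loglik=-30.0, loglik_null=-30.0, converged=True)
        assert nagelkerke_r2(fit) == pytest.approx(0.0)

    def test_perfect_model_gives_one(self):
        fit = LogisticFit(terms=["x"], columns=["x"],
                          params={"intercept": 0.0, "x": 1.0},
                          bse={"intercept": 1.0, "x": 1.0}, n_used=50,
                          loglik=0.0, loglik_null=-30.0, converged=True)
        assert nagelkerke_r2(fit) == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_formula_on_small_fit(self):
        frame = pd.DataFrame({
            "x": [0.1, 0.9, 0.4, 0.8, 0.2, 0.7, 0.3, 0.6, 0.5, 0.95],
            "cancer": [0, 1, 0, 1, 0, 1, 0, 0, 1, 1],
        })
        fit = fit_logistic(frame, ["x"])
        n = 10
        cs = 1 - math.exp(2 * (fit.loglik_null - fit.loglik) / n)
        expected = cs / (1 - math.exp(2 * fit.loglik_null / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-12)


class TestHosmerLemeshow:
    def test_two_group_hand_computation(self):
        frame = pd.DataFrame({
            "x": np.linspace(-2, 2, 40),
        })
        rng = np.random.default_rng(7)
        frame["cancer"] = (rng.random(40) < 1 / (1 + np.exp(-frame["x"]))).astype(float)
        fit = fit_logistic(frame, ["x"])
        stat, p = hosmer_lemeshow(fit, frame, groups=2)
        probs = predict_probability(fit, frame)
        order = np.argsort(probs, kind="mergesort")
        halves = [order[:20], order[20:]]
        expected_stat = 0.0
        for idx in halves:
            e1 = probs[idx].sum()
            o1 = frame["cancer"].to_numpy()[idx].sum()
            e0, o0 = len(idx) - e1, len(idx) - o1
            expected_stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert stat == pytest.approx(expected_stat, abs=1e-9)
        assert p == pytest.approx(float(chi2.sf(expected_stat, df=1)), abs=1e-12)

    def test_miscalibrated_model_rejected(self):
        rng = np.random.default_rng(13)
        n = 50_000
        frame = pd.DataFrame({"x": rng.uniform(-3, 3, n)})
        frame["cancer"] = (rng.random(n) < 1 / (1 + np.exp(-frame["x"]))).astype(float)
        bad = LogisticFit(terms=["x"], columns=["x"],
                          params={"intercept": 0.0, "x": 2.0},  # doubled slope
                          bse={"intercept": 1.0, "x": 1.0},
                          n_used=n, loglik=-1.0, loglik_null=-2.0, converged=True)
        _, p = hosmer_lemeshow(bad, frame)
        assert p < 0.05

    def test_calibrated_model_p_uniform(self):
        """P values from data simulated under the fitted model look uniform."""
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 2_000
            frame = pd.DataFrame({"x": rng.uniform(-2, 2, n)})
            frame["cancer"] = (rng.random(n) < 1 / (1 + np.exp(-1 + frame["x"]))).astype(float)
            fit = fit_logistic(frame, ["x"])
            pvals.append(hosmer_lemeshow(fit, frame)[1])
        assert kstest(pvals, "uniform").pvalue > 0.001
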