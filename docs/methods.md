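# Methods

## Scope

`reftriage` evaluates two-route referral triage for suspected breast
cancer. One row is one referral; repeat referrals of the same patient
are independent rows by design. The package compares three "models" of
the triage decision — the observed binary route, patient age as a raw
score, and a multivariable logistic risk score — on accuracy and on net
cost per referral under explicit cost–benefit assumptions.

## Synthetic cohort generator

No public registry of this kind exists, so the generator reproduces the
joint structure the analysis assumes. Per record, random draws are
consumed in a fixed order (age, menopause, TOP-T, TOP-O, TOP-P,
gravidity, breastfeeding, previous cancer, family history, HRT, outcome,
route), so a given `(config, seed)` is byte-stable across runs.

- **Age** is log-normal, fitted by least squares on the log scale to the
  quartiles (36, 46, 57) years, clipped to [1, 100]. Any three-quantile
  family would do; the log-normal is fixed and documented. The fitted
  parameters are μ = 3.818, σ = 0.341 on the log scale.
- **Menopause** is not drawn independently but as a logistic function of
  age with a fixed 4-year scale; its location is calibrated by root
  finding so the marginal equals 39.3%. The scale is a biological
  plausibility choice (menopausal transition spans roughly a decade),
  not an estimate.
- **Gravidity and breastfeeding** are coupled: breastfeeding is only
  possible when gravid, with the conditional rate chosen so the marginal
  (49.6%) is recovered. This constraint is biological, not estimated
  from data.
- **Other binaries and family history** are independent Bernoulli /
  categorical draws at their marginal frequencies (TOP-T 68.6%, TOP-O
  16.9%, TOP-P 33.3%, gravidity 82.6%, previous cancer 8.1%, HRT 8.7%;
  family history 67.2/16.9/15.9%).
- **Cancer** follows a logistic model in age, TOP-T, TOP-O, TOP-P and
  gravidity with per-predictor odds ratios (1.07/year, 4.85, 1.73, 0.46,
  0.72). The intercept is calibrated so the *population* prevalence
  equals the target (6.9%) — see below.
- **Route** is conditionally independent of covariates given the
  outcome: P(urgent | cancer) = 0.899, P(urgent | no cancer) = 0.595.
  The real referral process is feature-driven; this two-parameter
  simplification reproduces route-level accuracy exactly but makes the
  route uninformative beyond the outcome. Conclusions about *how* the
  route loses information to covariate-based scores therefore carry over
  only qualitatively.
- **Missingness** (`inject_missingness`) is missing-completely-at-random
  at the observed rates (50, 85, 88 per 7915 for gravidity,
  breastfeeding and family history); it is applied by the CLI
  `simulate` step, not inside `generate_cohort`.

### Intercept calibration

`calibrate_intercept` computes the population-average outcome
probability by deterministic quadrature: an 8001-point midpoint-quantile
grid over the clipped age distribution crossed with exact enumeration of
the binary-predictor combinations (independent generation makes the
combination weights products of marginals). Brent root finding on the
intercept (bracket [−50, 30], xtol 1e-10) makes that average equal the
target prevalence; the result is seed-free, cached per covariate-model
digest, and accurate to well under 1e-4. With all odds ratios at 1 it
reduces to logit(prevalence) exactly.

What the generator does **not** emulate: temporal drift in referral
criteria, patient-level correlation between repeat referrals,
feature-driven route selection, and any covariate–covariate association
beyond the two built-in couplings (menopause–age,
gravidity–breastfeeding). Passing tests show the pipeline is correct
under these stated conditions, not that the clinical conclusions hold in
any particular registry.

## Risk model construction

Fitting is maximum likelihood via IRLS (statsmodels GLM, binomial
family), with frequency-weight support so grouped 2×2 data reproduce the
cross-product odds ratio exactly. Wald z-tests and 95% CIs are reported
per coefficient; the univariable screen keeps candidates with
*P* < 0.250 (joint likelihood-ratio test for the three-level family
history); backward elimination repeatedly drops the term with the
largest *P* ≥ 0.050 (Wald for single-column terms, LR for multi-level
ones — the choice between Wald and LR for single terms is a convention;
both are implemented paths and the tests pin the Wald behaviour).
Complete cases only, fixed on the union of the starting predictors for
the elimination path; no imputation. Age enters linearly in log-odds
(a per-year odds ratio); no splines or interactions.

Numerical choices: convergence at relative log-likelihood change
< 1e-10 or 100 iterations; separation flagged when any |coefficient|
exceeds 15; rank-deficient designs rejected before fitting.

Diagnostics: Nagelkerke pseudo-R² (Cox–Snell scaled by its maximum) and
the Hosmer–Lemeshow test on ten equal-count risk groups (ties kept
together via quantile binning; groups with zero expected events or
non-events merged with a neighbour, with a warning; df = groups − 2).

## Accuracy statistics

Sensitivity, specificity, PPV and the false omission rate (FOR, the
share of routine referrals with a cancer outcome; 1 − NPV) with 95%
Clopper–Pearson intervals (Wilson optional). Zero denominators yield an
undefined ("n.a.") field rather than an error. Group comparisons use
Pearson χ² without continuity correction (appropriate at these sample
sizes) and the Mann–Whitney U test: exact enumeration of all group
labelings for combined n ≤ 20 (valid under ties), otherwise the
tie-corrected normal approximation without continuity correction.

## ROC and DeLong

AUC is the Mann–Whitney probability with half credit for ties —
identical to the trapezoidal area under the tie-grouped curve, and for a
binary rule exactly (sensitivity + specificity)/2. Variances and the
paired/unpaired z-tests use DeLong placement values; CIs are Wald on the
AUC scale truncated to [0, 1]. Published figures from other software may
use different small-sample CI conventions, so CI digits are not a
comparison target; note also that for a binary rule the analytic
identity (s + c)/2 takes precedence over any rounded published AUC.

## Cost engine

Net cost per referral is the cost-weighted sum of the confusion-matrix
proportions. ΔCost divides by the **absolute value** of the reference
cost: the published comparisons are only self-consistent under that
convention (e.g. −1.04 vs −0.86 → −21%, −0.29 vs −0.10 → −190%), and it
keeps "cheaper" negative regardless of the reference's sign.

`find_ort` evaluates every dichotomization at the unique observed score
values (rule: positive iff score ≥ t; the smallest value is the
all-positive policy) plus the all-negative policy — the empirical cost
is piecewise constant, so no interpolation is needed. Ties at the
minimal cost break toward the fewer urgent referrals (resource-sparing).
A limit worth noting: with an enormous false-negative cost a *binary*
score collapses to refer-all-urgent, while a continuous score merely
drives false negatives to zero at the lowest case score. `metz_slope`
exposes the classical decision-theoretic identity
((1 − π)/π)·((FPc − TNc)/(FNc − TPc)) linking the assumption to the ROC
slope at the optimum, used as a cross-check on smooth scores.

The default assumption grid is FNc:FPc ∈ {150, 100, 50, 1} crossed with
TPc:TNc ∈ {−1, −10}, anchored at FPc = 1 and TNc = −1.

## TOP stratification

`stratify_top` maps free-text symptom terms onto the three flags with a
fixed keyword table (palpable terms → T; visible nipple/skin/shape signs
→ O; felt sensations → P), case-insensitive whole-word matching with
plural/"-ing" stemming only, and one phrase rule ("skin thickening" is a
visible sign, bare "thickening" a palpable one). The source material
gives an open-ended ("includes …") list, so the table is necessarily a
judgement call; it is deliberately small, documented and frozen —
reproducibility over NLP sophistication. Unmatched terms warn and leave
flags unchanged.

## Problem sizes in tests and the acceptance script

Marginal-frequency checks use cohorts of 100 000–200 000; parameter
recovery uses 20 cohorts of 50 000 (fixed seeds 1–20) and the acceptance
script 5 cohorts of 50 000 — sizes at which the Monte-Carlo standard
error of each recovered odds ratio is a few percent, small enough to
separate estimator bias from noise while keeping the whole suite under a
minute. The qualitative AUC-ordering check uses n = 20 000, where the
paired DeLong comparisons are decisive.

## Known limitations

- The route mechanism is outcome-conditional, not feature-driven (above).
- Exact published AUCs (0.651 / 0.784 / 0.824) depend on the undeposited
  clinical dataset; only the ordering and route-level identities are
  reproducible, and emergent quantities (e.g. the cancer-group age
  distribution) are reported by the generator rather than forced.
- Clopper–Pearson CIs will not digit-match intervals produced by other
  software conventions.
- No regularized or Bayesian fitting; perfect separation is an error,
  not handled by penalization.
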