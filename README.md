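# reftriage

Cost-weighted evaluation of two-route cancer referral triage.

In the UK, primary-care referrals for suspected breast cancer are split
between an *urgent* two-week-wait route (U2WW) and a routine
*choose-and-book* (C&B) route. `reftriage` is a library and CLI for asking
whether that binary rule earns its keep: it compares the route decision,
patient age alone, and a multivariable logistic risk model (mMODEL) on
referral-level cohorts in terms of diagnostic accuracy, ROC/AUC with
DeLong tests, and — the core of the package — net cost per referral under
configurable cost–benefit assumptions, with an **optimal referral
threshold (ORT)** selected for each model and assumption. It is aimed at
clinical epidemiologists and health-services researchers evaluating
triage pathways.

## The model and the cost engine

Each referral carries age, the referral route, three non-exclusive
clinical-feature flags (TOP: **T**umour = palpable, **O**bservation =
visible, **P**erception = felt sensation), demographics and the cancer
outcome. The risk model is logistic regression built the classical way:
univariable screen (keep candidates with *P* < 0.250), then backward
elimination to *P* < 0.050, giving a predicted cancer probability per
referral.

A dichotomous triage rule has four outcomes with unit costs
(FNc, FPc, TPc, TNc), benefits entered as negative costs. Its net cost
per referral is

    cost = TPc·TPp + TNc·TNp + FPc·FPp + FNc·FNp

where TPp … FNp are the outcome proportions. The ORT of a score is the
cut-off minimizing this cost over every dichotomization "positive iff
score ≥ t" plus the two degenerate policies (refer all urgently / all
routinely). Models are compared by ΔCost = (cost − cost_ref)/|cost_ref| ×
100%, and by the standard assumption grid FNc:FPc ∈ {150, 100, 50, 1} ×
TPc:TNc ∈ {−1, −10} anchored at FPc = 1, TNc = −1.

Because the clinical registry behind such analyses is not public, the
package includes a synthetic-cohort generator that reproduces the
assumed structure: log-normal age matched to quartiles 36/46/57, binary
covariates at published marginal frequencies, cancer generated by a
logistic model (odds ratios: age 1.07/year, TOP-T 4.85, TOP-O 1.73,
TOP-P 0.46, gravidity 0.72) calibrated to 6.9% prevalence, and the route
drawn with sensitivity 89.9% / specificity 40.5% given the outcome.

## Worked example

```python
import numpy as np
from reftriage import (GeneratorConfig, generate_cohort, fit_logistic,
                       CostAssumption, find_ort, auc, delong_paired_test)
from reftriage.synthetic import outcome_probability

cfg = GeneratorConfig(n=20_000, seed=7)
frame = generate_cohort(cfg).frame

fit = fit_logistic(frame, ["age", "top_t", "top_o", "top_p", "gravidity"])
for name, (orv, lo, hi) in fit.odds_ratios().items():
    print(f"{name:10s} OR {orv:5.2f} (95% CI {lo:.2f}-{hi:.2f})")

risk = outcome_probability(cfg, {k: frame[k].to_numpy() for k in
                                 ("age", "top_t", "top_o", "top_p", "gravidity")})
age = frame["age"].to_numpy(float)
route = (frame["route"] == "urgent").to_numpy(float)
y = frame["cancer"].to_numpy(float)

a_m, a_age, z, p = delong_paired_test(risk, age, y)
print(f"AUC mMODEL {a_m:.3f} vs age {a_age:.3f}  (DeLong P = {p:.2g})")
print(f"AUC route  {auc(route, y).auc:.3f}")

assumption = CostAssumption.from_ratios(100, -1)   # FNc:FPc=100:1, TPc:TNc=-1:-1
for name, s in [("u2ww_route", route), ("age", age), ("mmodel", risk)]:
    res = find_ort(s, y, assumption)
    print(f"{name:10s} ORT {res.ort:8.3g}  urgent {100*res.urgent_fraction:5.1f}%  "
          f"net cost {res.net_cost:6.2f}")
```

Output:

```
age        OR  1.07 (95% CI 1.07-1.08)
top_t      OR  4.97 (95% CI 4.12-5.99)
top_o      OR  1.96 (95% CI 1.70-2.27)
top_p      OR  0.42 (95% CI 0.36-0.48)
gravidity  OR  0.70 (95% CI 0.60-0.82)
AUC mMODEL 0.842 vs age 0.797  (DeLong P = 2.5e-39)
AUC route  0.652
u2ww_route ORT        1  urgent  61.6%  net cost   0.80
age        ORT     37.8  urgent  70.7%  net cost   0.70
mmodel     ORT   0.0192  urgent  64.5%  net cost   0.45
```

The refitted odds ratios recover the generating values; the
multivariable score discriminates best (AUC 0.842 vs 0.797 vs 0.652);
and under a 100:1 false-negative-to-false-positive cost ratio both age
and the risk model dichotomized at their ORTs meet the cost challenge
more cheaply than the binary route (net cost 0.45 and 0.70 vs 0.80 per
referral).

The same pipeline is available from the shell:

```sh
reftriage simulate --n 8000 --seed 17 --out cohort.csv
reftriage evaluate --cohort cohort.csv --outdir report/
reftriage compare  --cohort cohort.csv --out compare.json
```

`evaluate` writes the full model × assumption comparison table
(`report.csv`/`report.json`): ORT, urgent fraction, accuracy parameters,
AUC, net cost and ΔCost per cell.

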