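# srsmeta

Sequential regression and simulation (SRS) for individual-participant
data pooled across randomized induction trials in moderate-to-severe
Crohn's disease — placebo-response normalization, drug-class effect
models, counterfactual subgroup discovery, cross-validated subgroup
validation, trial power simulation, and a per-patient treatment
recommender.

## Who this is for, and the problem it solves

Biologic drug classes for Crohn's disease (anti-TNF, anti-IL-12/23,
anti-integrin) were each tested against placebo, almost never against
each other, and placebo response varies across trials and calendar
time. Naively pooling participant-level data therefore confounds drug
effects with trial effects. SRS separates them with two nested linear
mixed models of the week-6 reduction in the Crohn's Disease Activity
Index (CDAI):

1. **Placebo model** — on placebo arms only:
   `Y = x'β_P + γ·year + u_trial + ε`, with nine baseline covariates
   (centered), study year, a trial random intercept
   `u_trial ~ N(0, τ²)`, and residual `ε ~ N(0, σ²)`.
2. **Drug-class models** — subtract each treated participant's
   predicted placebo-attributable response `ŷ_P = x'β̂_P` from the
   observed response and model the residual, drug-attributable
   reduction `R = Y − ŷ_P` per class with the same covariates (no
   year) and a trial random intercept.

Simulating all three counterfactual treatments per patient
(parametric bootstrap over the coefficient distribution, random
effects zero) and pairwise-testing the predictions at α = 0.05 yields
a preference pattern per patient — a weak ordering over the classes
such as `TNF > (IL = INT)` or `no preference` — and the patterns
partition the cohort into subgroups.

The raw trial data are access-restricted, so the package ships a
synthetic-cohort generator that reproduces the published per-trial
covariate summaries, arm sizes, and coefficient structure; every
stage of the pipeline is exercised and tested against it.

## Worked example

```python
import srsmeta as s
from srsmeta.decision import PatientInput, prepare_input

models = s.published_models()
patient = prepare_input(PatientInput(
    age=25, sex="male", bmi=24, crp=25, steroid=False, immunomod=False,
    tnf_history=False, ileal=True, baseline_cdai=430), 19.0)
rec = s.recommend(patient, models, mode="analytic")
print(rec.label)
for cls, p in rec.predictions.items():
    print(f"{cls:14s} {p.point:7.1f} +/- {p.se:5.1f} CDAI points")
```

prints

```
TNF > (IL = INT)
anti_tnf          79.2 +/-  12.8 CDAI points
anti_il1223        2.0 +/-  26.6 CDAI points
anti_integrin     34.5 +/-  11.3 CDAI points
```

A young biologic-naive patient with high disease activity (CDAI 430)
is predicted to gain ~79 points of drug-attributable CDAI reduction
from an anti-TNF — statistically distinguishable from both other
classes at α = 0.05, hence the label putting TNF alone on top, while
anti-IL-12/23 and anti-integrin are indistinguishable from each
other. (These drug-attributable points come on top of the
placebo-attributable response, ~75 points for the reference patient.)

The `examples/` directory has one short script per capability:
cohort generation, sequential model fitting, subgroup assignment,
cross-validation, power simulation, and recommendation. A thin CLI
mirrors the pipeline (`srsmeta generate | harmonize | fit | assign |
crossvalidate | power | recommend`); `srsmeta recommend --help` shows
the dashboard-style patient flags.

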