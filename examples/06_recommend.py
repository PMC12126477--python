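"""Per-patient treatment recommendation.

Drives the decision-support layer with the packaged published models:
a 58-year-old woman with prior anti-TNF exposure on steroids (the
profile of the published anti-IL-12/23-preferring subgroup) and a
young biologic-naive patient with high disease activity (a typical
anti-TNF responder).  Points are drug-attributable CDAI reductions;
the pairwise tests at alpha = 0.05 produce the preference label.

Note the packaged models carry only the published per-term standard
errors (a diagonal covariance — the off-diagonal covariances were
never published), which overstates prediction uncertainty: the older
woman's anti-IL-12/23 advantage is numerically large (~50 points) but
not statistically resolved here, whereas models refit on a cohort
(see example 02) carry the full covariance and resolve more
preferences.
"""

import srsmeta as s
from srsmeta.decision import PatientInput, prepare_input

models = s.published_models()

older_woman = prepare_input(PatientInput(
    age=58, sex="female", bmi=22, crp=25, steroid=True, immunomod=False,
    tnf_history=True, ileal=True, baseline_cdai=260), 19.0)
young_naive = prepare_input(PatientInput(
    age=25, sex="male", bmi=24, crp=25, steroid=False, immunomod=False,
    tnf_history=False, ileal=True, baseline_cdai=430), 19.0)

for name, patient in [("58F, prior anti-TNF, steroids", older_woman),
                      ("25M, biologic-naive, CDAI 430", young_naive)]:
    rec = s.recommend(patient, models, mode="analytic")
    print(f"\n{name}: {rec.label}")
    print(f"  {rec.narrative}")
    for cls, p in rec.predictions.items():
        print(f"  {cls:14s} {p.point:7.1f} +/- {p.se:5.1f} CDAI points")
    for w in rec.warnings:
        print(f"  warning: {w}")
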