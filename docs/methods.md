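# Methods

## The problem and the model

Pooled participant-level data from placebo-controlled induction trials
in moderate-to-severe Crohn's disease cannot be compared naively:
placebo response differs across trials and calendar time, and the drug
classes were tested against placebo, not against each other. The
package implements sequential regression and simulation (SRS), a
two-stage normalization:

1. **Placebo stage.** On the placebo arms, fit a linear mixed model of
   the week-6 CDAI reduction `Y`:

   `Y = x'β_P + γ·year + u_trial + ε`,  `u_trial ~ N(0, τ²)`, `ε ~ N(0, σ²)`

   with nine fixed covariates (baseline CDAI, age, BMI, CRP, prior
   anti-TNF use, sex, steroid use, immunomodulator use, ileal
   involvement) plus study year. Continuous covariates are centered at
   the pooled means of the fitting sample; the centers are persisted
   with the model and reused for every later prediction, never
   recomputed.

2. **Drug stage.** For every actively treated participant, predict the
   placebo-attributable reduction `ŷ_P = x'β̂_P` (random effects set
   to 0), subtract it from the observed reduction, and fit one mixed
   model per drug class (anti-TNF, anti-IL-12/23, anti-integrin) on
   the residual, drug-attributable reduction, with the same nine
   covariates and a trial random intercept but no year term (too
   little calendar spread within a class).

Estimation is REML via `statsmodels.MixedLM`. The profile likelihood
is optimized with Powell's method first (gradient-based optimizers can
park on a degenerate boundary where the intercept is absorbed into the
random effects), falling back to Nelder–Mead and then L-BFGS, taking
the first converged fit. The fixed-effect covariance is computed
directly as `(X'Σ⁻¹X)⁻¹` by a per-trial Woodbury identity rather than
from the optimizer's Hessian, which degenerates when the
random-intercept variance is estimated at zero — routine with nine
placebo trials and a small true τ.

Model comparison uses a likelihood-ratio test against an
intercept-only model, both refit with full ML on identical rows;
per-term inference uses Wald tests with the large-sample normal
reference.

## Subgroups

For each participant the three drug-class models give counterfactual
conditional-mean predictions. Uncertainty comes from a parametric
bootstrap: coefficient vectors drawn from `MVN(β̂, V̂)` (random effects
zero), summarised as the median (point) and SD (standard error) of the
draws; a closed form `sqrt(x'V̂x)` serves real-time use and as the
oracle the bootstrap is tested against. Case-resampling with refits
was rejected: 10,000 refits per patient is infeasible, and the
marginal (random-effects-zero) prediction makes coefficient-space
sampling the natural reading.

Each unordered pair of classes is compared with the two-sample normal
statistic `z = (p_a − p_b)/sqrt(se_a² + se_b²)` at a nominal two-sided
alpha of 0.05. The source analysis describes paired t-tests; since
each patient's predictions are summaries (median, SE) of independent
coefficient draws, the two-sample normal form is the only statistic
computable from those summaries, and it is what this package uses.

The triple of pairwise outcomes maps deterministically onto one of 27
cells. Thirteen correspond to weak orderings of the three classes
(e.g. `TNF > (IL = INT)`, `no preference` when all three are
indistinguishable); the remaining fourteen — strict cycles and
tie-intransitive patterns such as A>B, A~C, B~C — are labeled
`inconsistent` and reported separately. On synthetic cohorts at the
published size this bucket is sizable (roughly a fifth of patients),
because indistinguishability is not transitive; the published subgroup
table reports none, which suggests its categories were coarser than
the raw outcome triples. The census therefore reports, besides label
counts, a "best or tied for best" aggregate that follows the published
grouping convention — a top-tier tie involving the anti-integrin class
is filed under "other" and credited to neither tied class — plus the
unfiltered top-tier-contains count for each class.

## Synthetic-trial generator

The generator emulates the 15-trial pooled cohort: per-trial arm
sizes, covariate means/SDs and proportions as published, and outcomes
composed of the placebo linear predictor, the arm's drug-class linear
predictor, trial random intercepts, and Gaussian residual noise.

Distributional choices and defaults:

- **Age, BMI**: normals truncated to plausibility bounds (18–90 years,
  14–60 kg/m²). **Baseline CDAI**: normal truncated to the [220, 450]
  eligibility window. Truncation parameters are moment-matched so the
  realized mean/SD reproduce the configured ones (naive truncation
  would shift the mean by ~10 CDAI points); where the published SD
  exceeds what a truncated normal on the window can attain (several
  CDAI columns sit near that ceiling), the mean is matched exactly and
  the SD gets as close as the family allows.
- **CRP**: moment-matched gamma — right-skewed and nonnegative, with
  only mean/SD published.
- **Residual SDs**: σ_placebo = 90 CDAI points, motivated by the
  published placebo-model cross-validated RMSE of ~93; σ_drug = 40 per
  class (unpublished; chosen so active-arm outcomes are noisier than
  placebo outcomes without drowning the class effects). Active-arm
  noise combines both: `sqrt(σ_P² + σ_D²)`.
- **Trial random-intercept SD**: τ = 9.5, set so the trial effect
  carries ~1% of total placebo-response variance, matching the
  published variance partition. All of these are configuration, not
  hard-coded.
- **Missingness**: independent blanking at 0.4% per continuous
  covariate (≈3% of participants with ≥1 missing covariate), 0.2% per
  boolean, 11% for the week-6 CDAI and 2% for week-4. Early anti-TNF
  trials that never recorded prior-exposure history (ACCENT, PRECISE1,
  SONIC in the packaged table) have the flag blanked wholesale.
- **Week-4 CDAI** is baseline minus 0.7 of the week-6 reduction plus
  N(0, 10) noise. It exists only so LOCF has something to carry
  forward; no week-4 trajectory is modeled. A consequence worth
  knowing: with the default 11% missing week-6 outcomes, LOCF imputes
  a value carrying ~70% of the signal, attenuating fitted slopes by
  ~3%. The parameter-recovery experiment therefore generates outcomes
  complete (harmonization robustness is exercised separately); tests
  passing on the generator say nothing about LOCF behavior on real
  longitudinal trajectories.

What the generator does **not** emulate: covariate correlations within
trial (everything is drawn independently given the trial), dropout
mechanisms beyond independent blanking, longitudinal trajectories, and
adverse events. Subgroup prevalences are therefore not comparable to
the published ones — the published anti-IL-12/23-preferring subgroup
(139/5703) depends on the joint covariate structure of the real
cohort, and at the published sample size its synthetic counterpart's
size fluctuates strongly with the estimation noise of the small
anti-IL class (≈590 active participants).

## Harmonization

Pooled-median imputation for continuous covariates; records with any
missing boolean covariate dropped; week-6 reduction computed from the
week-6 CDAI when present, else carried forward from week 4, else the
record is excluded from modeling (no rule exists for total absence of
follow-up, and mean imputation would bias the outcome model). Order is
fixed: deterministic anti-TNF-history imputation first (so those
records are not swept up by the categorical drop), then median
imputation and the drop, then LOCF. The pipeline is idempotent and
never alters an observed value.

## Validation

Cross-validation refits the entire sequential pipeline per fold;
folds are participant-level but stratified by trial so every training
split retains all trials (random-intercept estimability), and
centering constants are recomputed from each fold's training sample.
Concordance between two assignment runs is 1 minus the fraction of
patients with a strict pairwise reversal; a superiority that becomes a
tie is lost power, not a contradiction. Alternative model families
plug in through a three-method contract (fit / predict /
predict_uncertainty); the shipped `ResamplingPredictor` wraps any
sklearn-style regressor with bootstrap-resampling uncertainty. A tuned
tree ensemble is deliberately not shipped: its published concordance
figure depends on the real data, and an untuned stand-in would invite
false comparisons.

## Power simulation

Arms are bootstrapped (with replacement) from a filtered reference
population; each sampled patient's expected reduction is placebo plus
class prediction, converted to a clinical-response probability
`P(reduction ≥ 100) = 1 − Φ((100 − μ)/σ)` under conditional normality
with `σ = sqrt(σ²_P + σ²_class)` from the fitted models (a
`class_only` switch exists). Responder counts per arm are compared by
a 2×2 chi-squared test without continuity correction at alpha 0.05;
power is the rejection fraction over 1000 simulations by default.

Counts can be formed two ways. The default follows the stated
procedure: the expected count, `round(arm size × mean probability)`.
Because the spread of per-patient probabilities is narrower than
binomial noise, the test is *conservative* under the null in this
mode — and, since the only randomness left is the resampling spread
of the arm-mean probability, power behaves almost like a step
function of arm size, snapping from ~0 to ~1 once the deterministic
chi-squared statistic crosses its critical value. The `observed` mode draws each patient's responder status
Bernoulli(p), making the count variance exactly binomial — that is the
mode in which the nominal level holds and in which calibration is
tested. The published 87%/97% power figures depend on the real
covariate distribution and are not reproduced; the calibration and
arm-size/enrichment monotonicity properties stand in.

## Decision support

The recommendation layer mirrors the dashboard rules: all inputs
mandatory except baseline CDAI (imputed as 300, moderate-to-severe)
and CRP (imputed as the pooled reference median); a missing mandatory
field is an error naming the field; supplied values are never
overridden. Predictions use the analytic SE by default for real-time
use (bootstrap mode available; the two agree at 10,000 draws), and
warnings fire when an input leaves the training envelope (e.g.
baseline CDAI outside [220, 450]). Entered values are taken at face
value — a user entering 0 for an unknown numeric field gets a
prediction at 0 with a warning, not silent re-imputation. A minimal
OMOP-shaped CSV reader (person / measurement / drug-exposure) is
provided as a stub input path; real EHR connectivity is out of scope.

## Problem sizes and numerical choices

- Parameter recovery: 25 replicate cohorts, ~50,000 participants per
  model (placebo pool and each class pool), arms scaled proportionally
  from the published per-trial sizes. 25 replicates is the package's
  chosen balance between the Monte-Carlo precision the integer-valued
  recovery checks need and a desk-scale runtime; a 40-replicate
  placebo-only audit confirmed the estimator unbiased (all slope z
  below 2).
- Cross-validation structural checks run on a cohort scaled to ~5,700
  per model pool (~23,000 records): at the published size, whether the
  small anti-IL subgroup is detected at all depends on one realization
  of the anti-IL model's estimation noise; at the scaled size its
  presence reflects the configured effect structure.
- LRT calibration: 150 null replicates of ~1,560 placebo participants
  across six trials; power-simulation calibration: 1000 simulations.
- Exact ties with zero SE compare as indistinguishable; cyclic and
  tie-intransitive outcome triples are labeled inconsistent, never
  silently folded into a preference.
- Bootstrap draws use per-patient seed substreams
  (`SeedSequence([seed, patient index, class index])`), so results are
  independent of evaluation order.

## Known limitations

- Independent covariates within trial make synthetic subgroup sizes
  and prevalences incomparable to the published cohort's.
- The placebo model's ŷ_P used for residualization sets random effects
  to zero by default; a switch adds fitted trial intercepts, but the
  published choice is not stated beyond the subgroup-assignment
  convention.
- Wald p-values use the normal reference; no small-sample df
  correction.
- The expected-count power mode is conservative under the null by
  construction (see above).
- Single-trial drug classes fall back to a fixed-effects-only fit with
  a loud log message rather than failing.
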