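"""Synthetic trial-cohort generator.

Emulates the statistical structure the downstream analysis assumes: one
row per participant across a set of induction trials, baseline
covariates drawn per trial from the published per-trial summaries, and
a week-6 CDAI reduction composed of a placebo-attributable linear
predictor, a drug-class-attributable linear predictor (active arms
only), trial random intercepts, and Gaussian residual noise.  Baseline
CDAI is truncated to the [220, 450] eligibility window.

Distributional choices
----------------------
Age and BMI are normals truncated to plausibility bounds (age 18-90,
BMI 14-60); baseline CDAI is a normal truncated to the eligibility
window; CRP is a moment-matched gamma (right-skewed, nonnegative — the
published tables give only means and SDs).  Binary covariates are
Bernoulli at the published proportions.

The linear predictors center continuous covariates at the configured
population means (weighted across trials), mirroring the pooled
centering used when fitting.  Year enters the placebo predictor only.

A week-4 CDAI is generated as baseline minus a fraction (default 0.7)
of the week-6 reduction plus small noise; it exists so that
last-observation-carried-forward has something to carry forward, not as
a model of the week-4 trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import constants
from .schema import (CDAI_ELIGIBILITY, DRUG_CLASSES, PLACEBO,
                     CohortTable, cohort_digest)

AGE_BOUNDS = (18.0, 90.0)
BMI_BOUNDS = (14.0, 60.0)
CDAI_BOUNDS = CDAI_ELIGIBILITY


class ConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class TrialConfig:
    """Covariate distribution and arm sizes for one synthetic trial."""

    trial_id: str
    year: int
    drug_class: str
    n_active: int
    n_placebo: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    cdai_mean: float
    cdai_sd: float
    crp_mean: float
    crp_sd: float
    p_female: float
    p_tnf_history: float
    p_steroid: float
    p_immunomod: float
    p_ileal: float
    #: False for early anti-TNF trials that never recorded prior-exposure
    #: history; missingness injection blanks the flag for every record
    tnf_history_recorded: bool = True


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic-cohort generator.

    Coefficient sets are maps term -> CDAI points per (centered) unit.
    ``tau_*`` are trial random-intercept SDs and ``sigma_*`` residual
    SDs, all in CDAI points.
    """

    trials: tuple[TrialConfig, ...]
    beta_placebo: dict[str, float]
    beta_drug: dict[str, dict[str, float]]
    tau_placebo: float = 9.5
    tau_drug: dict[str, float] = field(
        default_factory=lambda: {c: 9.5 for c in DRUG_CLASSES})
    sigma_placebo: float = 90.0
    sigma_drug: dict[str, float] = field(
        default_factory=lambda: {c: 40.0 for c in DRUG_CLASSES})
    missing_covariate_rate: float = 0.004
    missing_categorical_rate: float = 0.002
    missing_week4_rate: float = 0.02
    missing_week6_rate: float = 0.11
    week4_fraction: float = 0.7
    week4_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ConfigError("config has no trials")
        for t in self.trials:
            if t.n_active + t.n_placebo < 1:
                raise ConfigError(f"trial {t.trial_id}: no participants")
            if t.drug_class not in DRUG_CLASSES:
                raise ConfigError(f"trial {t.trial_id}: unknown drug class "
                                  f"{t.drug_class!r}")
            for name in ("age_sd", "bmi_sd", "cdai_sd", "crp_sd"):
                if getattr(t, name) < 0:
                    raise ConfigError(f"trial {t.trial_id}: negative {name}")
            for name in ("p_female", "p_tnf_history", "p_steroid",
                         "p_immunomod", "p_ileal"):
                p = getattr(t, name)
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"trial {t.trial_id}: {name}={p} not in [0,1]")
        for name in ("tau_placebo", "sigma_placebo", "week4_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative {name}")
        for name in ("missing_covariate_rate", "missing_categorical_rate",
                     "missing_week4_rate", "missing_week6_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name}={r} not in [0,1]")
        if set(self.beta_drug) != set(DRUG_CLASSES):
            raise ConfigError("beta_drug must name exactly the three drug classes")

    # -- centering ---------------------------------------------------------

    def population_centers(self) -> dict[str, float]:
        """Size-weighted population means of the continuous covariates."""
        w = np.array([t.n_active + t.n_placebo for t in self.trials], float)
        w /= w.sum()

        def wmean(attr):
            return float(np.dot(w, [getattr(t, attr) for t in self.trials]))

        return {
            "year": float(np.dot(w, [t.year for t in self.trials])),
            "age": wmean("age_mean"),
            "bmi": wmean("bmi_mean"),
            "baseline_cdai": wmean("cdai_mean"),
            "crp": wmean("crp_mean"),
        }

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["trials"] = tuple(TrialConfig(**t) for t in d["trials"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_config(seed: int = 0) -> GeneratorConfig:
    """Generator configured to the published cohort: the 15 trials'
    covariate summaries and arm sizes, and the published coefficient
    sets as ground truth."""
    consts = constants.published_constants()
    trials = tuple(
        TrialConfig(
            trial_id=t.trial_id, year=t.year, drug_class=t.drug_class,
            n_active=t.n_active, n_placebo=t.n_placebo,
            age_mean=t.age[0], age_sd=t.age[1],
            bmi_mean=t.bmi[0], bmi_sd=t.bmi[1],
            cdai_mean=t.baseline_cdai[0], cdai_sd=t.baseline_cdai[1],
            crp_mean=t.crp[0], crp_sd=t.crp[1],
            p_female=t.p_female, p_tnf_history=t.p_tnf_history,
            p_steroid=t.p_steroid, p_immunomod=t.p_immunomod,
            p_ileal=t.p_ileal,
            tnf_history_recorded=t.trial_id not in constants.PRE_APPROVAL_TRIALS,
        )
        for t in consts.trial_table)
    return GeneratorConfig(
        trials=trials,
        beta_placebo=consts.coefficients(PLACEBO),
        beta_drug={c: consts.coefficients(c) for c in DRUG_CLASSES},
        seed=seed)


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with all noise and missingness switched off."""
    return replace(config,
                   tau_placebo=0.0, sigma_placebo=0.0,
                   tau_drug={c: 0.0 for c in DRUG_CLASSES},
                   sigma_drug={c: 0.0 for c in DRUG_CLASSES},
                   week4_noise_sd=0.0,
                   missing_covariate_rate=0.0, missing_categorical_rate=0.0,
                   missing_week4_rate=0.0, missing_week6_rate=0.0)


# ---------------------------------------------------------------------------
# covariate generation
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=512)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float
                      ) -> tuple[float, float]:
    """Location/scale of the untruncated normal whose truncation to
    [lo, hi] best reproduces the requested mean and SD.

    Naive truncation shifts the realized mean away from the published
    one (by ~10 CDAI points for baseline CDAI), so the parameters are
    moment-matched.  When the requested SD exceeds what a truncated
    normal on the interval can attain (the published baseline-CDAI SDs
    sit near that ceiling), the fit matches the mean and gets as close
    to the SD as the family allows — the mean error is weighted up to
    make it the binding constraint.
    """
    from scipy import optimize

    def resid(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale,
                                     moments="mv")
        return [10.0 * (float(m) - mean) / sd,
                (float(np.sqrt(v)) - sd) / sd]

    sol = optimize.least_squares(
        resid, x0=[mean, np.log(sd)],
        bounds=([lo - 5 * sd, np.log(sd / 10.0)],
                [hi + 5 * sd, np.log(sd * 20.0)]))
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    loc, scale = _truncnorm_params(float(mean), float(sd), float(lo),
                                   float(hi))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def _gamma_from_moments(rng, mean, sd, size):
    if sd == 0 or mean <= 0:
        return np.full(size, max(mean, 0.0))
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size)


def generate_covariates(config: GeneratorConfig,
                        seed: int | None = None) -> CohortTable:
    """Draw baseline covariates for every participant of every trial.

    Deterministic given ``seed`` (defaults to ``config.seed``).  Arm
    labels are assigned within trial: ``n_placebo`` placebo rows then
    ``n_active`` rows of the trial's drug class.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DA]))
    frames = []
    for t in config.trials:
        n = t.n_active + t.n_placebo
        df = pd.DataFrame({
            "trial_id": t.trial_id,
            "year": t.year,
            "arm": [PLACEBO] * t.n_placebo + [t.drug_class] * t.n_active,
            "age": _truncnorm(rng, t.age_mean, t.age_sd, *AGE_BOUNDS, size=n),
            "sex": np.where(rng.random(n) < t.p_female, "female", "male"),
            "bmi": _truncnorm(rng, t.bmi_mean, t.bmi_sd, *BMI_BOUNDS, size=n),
            "baseline_cdai": _truncnorm(rng, t.cdai_mean, t.cdai_sd,
                                        *CDAI_BOUNDS, size=n),
            "crp": _gamma_from_moments(rng, t.crp_mean, t.crp_sd, size=n),
            "tnf_history": rng.random(n) < t.p_tnf_history,
            "steroid": rng.random(n) < t.p_steroid,
            "immunomod": rng.random(n) < t.p_immunomod,
            "ileal": rng.random(n) < t.p_ileal,
        })
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant_id",
               [f"P{i:06d}" for i in range(len(out))])
    cohort = CohortTable(out, provenance=f"generated seed={seed}")
    cohort.provenance += f" digest={cohort_digest(cohort.records)}"
    return cohort


# ---------------------------------------------------------------------------
# outcome simulation
# ---------------------------------------------------------------------------

def _linear_predictor(df: pd.DataFrame, beta: dict[str, float],
                      centers: dict[str, float]) -> np.ndarray:
    eta = np.full(len(df), beta.get("intercept", 0.0))
    for term, b in beta.items():
        if term == "intercept" or b == 0.0:
            continue
        if term == "sex_male":
            x = (df["sex"].to_numpy() == "male").astype(float)
        elif term in ("tnf_history", "steroid", "immunomod", "ileal"):
            x = df[term].to_numpy(dtype=float)
        else:  # continuous, centered
            x = df[term].to_numpy(dtype=float) - centers[term]
        eta = eta + b * x
    return eta


def simulate_outcomes(cohort: CohortTable, config: GeneratorConfig,
                      seed: int | None = None) -> CohortTable:
    """Attach week-6 (and week-4) CDAI outcomes to a complete cohort.

    reduction_week6 = placebo predictor + [active] x drug predictor
    + trial random intercepts + Normal residual, with the residual SD
    combining the placebo and drug components on active arms.
    """
    if seed is None:
        seed = config.seed
    df = cohort.records
    covcols = ["age", "bmi", "baseline_cdai", "crp",
               "tnf_history", "steroid", "immunomod", "ileal"]
    if df[covcols].isna().any().any():
        raise ValueError("cohort has missing covariates; simulate outcomes "
                         "before injecting missingness")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0457]))
    centers = config.population_centers()
    out = df.copy()

    beta_p = dict(config.beta_placebo)
    eta = _linear_predictor(out, {k: v for k, v in beta_p.items()
                                  if k != "year"}, centers)
    eta = eta + beta_p.get("year", 0.0) * (out["year"].to_numpy(dtype=float)
                                           - centers["year"])

    # per-trial random intercepts, one draw per trial per component
    trial_ids = [t.trial_id for t in config.trials]
    re_placebo = dict(zip(trial_ids,
                          rng.normal(0.0, config.tau_placebo, len(trial_ids))))
    re_drug = {c: dict(zip(trial_ids,
                           rng.normal(0.0, config.tau_drug[c], len(trial_ids))))
               for c in DRUG_CLASSES}
    eta = eta + out["trial_id"].map(re_placebo).to_numpy(dtype=float)

    sd = np.full(len(out), config.sigma_placebo, dtype=float)
    active = out["arm"].to_numpy() != PLACEBO
    for cls in DRUG_CLASSES:
        in_cls = out["arm"].to_numpy() == cls
        if not in_cls.any():
            continue
        eta_d = _linear_predictor(out.loc[in_cls], config.beta_drug[cls],
                                  centers)
        eta_d = eta_d + out.loc[in_cls, "trial_id"].map(
            re_drug[cls]).to_numpy(dtype=float)
        eta[in_cls] += eta_d
        sd[in_cls] = np.hypot(config.sigma_placebo, config.sigma_drug[cls])

    reduction = eta + rng.normal(0.0, 1.0, len(out)) * sd
    out["reduction_week6"] = reduction
    out["cdai_week6"] = out["baseline_cdai"] - reduction
    out["cdai_week4"] = (out["baseline_cdai"]
                         - config.week4_fraction * reduction
                         + rng.normal(0.0, config.week4_noise_sd, len(out)))
    return CohortTable(out, provenance=cohort.provenance + " +outcomes")


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(cohort: CohortTable, config: GeneratorConfig,
                       seed: int | None = None) -> CohortTable:
    """Blank fields at the configured independent rates.

    Continuous covariates at ``missing_covariate_rate`` each, boolean
    covariates at ``missing_categorical_rate`` each, and follow-up CDAI
    at the week-4/week-6 rates.  Trials whose ``tnf_history_recorded``
    flag is False get their anti-TNF-history column blanked wholesale
    (the downstream deterministic imputation restores it as False).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3155]))
    out = cohort.records.copy()
    n = len(out)
    for col in ("age", "bmi", "baseline_cdai", "crp"):
        if config.missing_covariate_rate > 0:
            out.loc[rng.random(n) < config.missing_covariate_rate, col] = np.nan
    for col in ("tnf_history", "steroid", "immunomod", "ileal"):
        if config.missing_categorical_rate > 0:
            out.loc[rng.random(n) < config.missing_categorical_rate, col] = pd.NA
    if config.missing_week4_rate > 0:
        out.loc[rng.random(n) < config.missing_week4_rate, "cdai_week4"] = np.nan
    if config.missing_week6_rate > 0:
        blank6 = rng.random(n) < config.missing_week6_rate
        out.loc[blank6, "cdai_week6"] = np.nan
        out.loc[blank6, "reduction_week6"] = np.nan
    unrecorded = {t.trial_id for t in config.trials
                  if not t.tnf_history_recorded}
    if unrecorded:
        out.loc[out["trial_id"].isin(unrecorded), "tnf_history"] = pd.NA
    return CohortTable(out, provenance=cohort.provenance + " +missingness")


def generate_cohort(config: GeneratorConfig,
                    seed: int | None = None) -> CohortTable:
    """Covariates, outcomes and missingness in one call."""
    cohort = generate_covariates(config, seed)
    cohort = simulate_outcomes(cohort, config, seed)
    return inject_missingness(cohort, config, seed)
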