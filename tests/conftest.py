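import pytest
from dataclasses import replace

import srsmeta as s
from srsmeta.constants import PRE_APPROVAL_TRIALS
from srsmeta.generator import GeneratorConfig, TrialConfig

_YEARS = {"anti_il1223": (2008, 2011), "anti_integrin": (2001, 2008),
          "anti_tnf": (1999, 2003)}


def make_small_config(seed=7, n_active=80, n_placebo=40, **overrides):
    """Six synthetic trials (two per drug class) with pooled-cohort-like
    covariate distributions; small enough for fast unit tests."""
    consts = s.published_constants()
    trials = []
    for cls in s.DRUG_CLASSES:
        for j, yr in enumerate(_YEARS[cls]):
            trials.append(TrialConfig(
                trial_id=f"{cls[5:].upper()}{j}", year=yr, drug_class=cls,
                n_active=n_active, n_placebo=n_placebo,
                age_mean=37, age_sd=12, bmi_mean=24, bmi_sd=5,
                cdai_mean=305, cdai_sd=60, crp_mean=19, crp_sd=25,
                p_female=0.45, p_tnf_history=0.4, p_steroid=0.45,
                p_immunomod=0.35, p_ileal=0.75))
    cfg = GeneratorConfig(
        trials=tuple(trials),
        beta_placebo=consts.coefficients("placebo"),
        beta_drug={c: consts.coefficients(c) for c in s.DRUG_CLASSES},
        seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = s.generate_cohort(small_config, small_config.seed)
    clean, _ = s.harmonize(cohort)
    return clean


@pytest.fixture(scope="session")
def default_cohort_raw():
    """Synthetic cohort at the published per-trial arm sizes."""
    cfg = s.default_config(0)
    return s.generate_cohort(cfg, 0)


@pytest.fixture(scope="session")
def default_cohort(default_cohort_raw):
    clean, _ = s.harmonize(default_cohort_raw, PRE_APPROVAL_TRIALS)
    return clean


@pytest.fixture(scope="session")
def default_models(default_cohort):
    placebo, drugs, resid = s.fit_all(default_cohort)
    return placebo, drugs, resid


@pytest.fixture()
def published_models():
    # function-scoped: a few tests perturb the covariance in place
    return s.published_models()


@pytest.fixture()
def reference_patient():
    """Covariate-wise center of the published cohort: continuous
    covariates at the pooled means, female, all history/treatment
    flags false."""
    from srsmeta.constants import population_centers
    rec = dict(population_centers())
    rec.update(sex="female", tnf_history=False, steroid=False,
               immunomod=False, ileal=False)
    return rec
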