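"""Synthetic-cohort generator: distributions, outcome model, missingness."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import srsmeta as s
from srsmeta.generator import (ConfigError, GeneratorConfig, TrialConfig,
                               noiseless)
from srsmeta.schema import CohortTable
from tests.conftest import make_small_config


def _single_trial_config(**kw):
    """One noiseless placebo+active trial whose covariate means define
    the centered reference patient."""
    defaults = dict(trial_id="T", year=2006, drug_class="anti_tnf",
                    n_active=1, n_placebo=1,
                    age_mean=37.0, age_sd=0.0, bmi_mean=24.0, bmi_sd=0.0,
                    cdai_mean=300.0, cdai_sd=0.0, crp_mean=19.0, crp_sd=0.0,
                    p_female=1.0, p_tnf_history=0.0, p_steroid=0.0,
                    p_immunomod=0.0, p_ileal=0.0)
    defaults.update(kw)
    consts = s.published_constants()
    cfg = GeneratorConfig(
        trials=(TrialConfig(**defaults),),
        beta_placebo=consts.coefficients("placebo"),
        beta_drug={c: consts.coefficients(c) for c in s.DRUG_CLASSES})
    return noiseless(cfg)


def test_determinism_byte_identical(small_config):
    a = s.generate_cohort(small_config, 11)
    b = s.generate_cohort(small_config, 11)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_different_seeds_differ(small_config):
    a = s.generate_covariates(small_config, 1)
    b = s.generate_covariates(small_config, 2)
    assert not a.records["age"].equals(b.records["age"])


def test_eligibility_truncation_never_violated(default_cohort_raw):
    df = default_cohort_raw.records
    assert df["baseline_cdai"].dropna().between(220, 450).all()
    assert df["age"].dropna().between(18, 90).all()
    assert df["bmi"].dropna().between(14, 60).all()
    assert (df["crp"].dropna() >= 0).all()


def test_generated_age_matches_configured_mean():
    """UNITI1-like trial (age 37 +/- 12, n = 502): the mean generated
    age over 10 seeds stays within a 3-SE Monte-Carlo band of 37."""
    cfg = make_small_config()
    trial = replace(cfg.trials[0], n_active=252, n_placebo=250,
                    age_mean=37.0, age_sd=12.0)
    cfg = replace(cfg, trials=(trial,) + cfg.trials[1:])
    means = []
    for seed in range(10):
        df = s.generate_covariates(cfg, seed).records
        means.append(df.loc[df["trial_id"] == trial.trial_id, "age"].mean())
    se = 12.0 / np.sqrt(502 * 10)
    assert abs(np.mean(means) - 37.0) < 3 * se


def test_noiseless_reference_patient_reductions():
    """With all noise off and a patient at the covariate center, the
    simulated reduction equals the published intercepts: 74.69 on
    placebo and 74.69 + 54.96 on an anti-TNF arm."""
    cfg = _single_trial_config()
    cohort = s.generate_covariates(cfg, 0)
    out = s.simulate_outcomes(cohort, cfg, 0).records
    assert out.loc[out["arm"] == "placebo", "reduction_week6"].iloc[0] \
        == pytest.approx(74.69, abs=1e-9)
    assert out.loc[out["arm"] == "anti_tnf", "reduction_week6"].iloc[0] \
        == pytest.approx(74.69 + 54.96, abs=1e-9)


def test_noiseless_cdai_gradient_is_33_per_100():
    """A placebo patient 100 CDAI points above center improves 33
    points more than the reference patient."""
    cfg = _single_trial_config()
    cohort = s.generate_covariates(cfg, 0)
    bumped = cohort.records.copy()
    bumped["baseline_cdai"] += 100.0
    r0 = s.simulate_outcomes(cohort, cfg, 0).records
    r1 = s.simulate_outcomes(CohortTable(bumped), cfg, 0).records
    diff = (r1["reduction_week6"] - r0["reduction_week6"]).to_numpy()
    placebo = (r0["arm"] == "placebo").to_numpy()
    assert np.allclose(diff[placebo], 33.0)
    # active arms add their own baseline-CDAI gradient on top
    assert np.allclose(diff[~placebo],
                       33.0 + 100 * cfg.beta_drug["anti_tnf"]["baseline_cdai"])


@pytest.mark.parametrize("field,delta", [
    ("age", 10.0), ("bmi", 2.0), ("crp", 5.0), ("baseline_cdai", 50.0)])
def test_noiseless_outcome_exactly_linear(field, delta):
    """Coefficient-by-coefficient: perturbing one covariate moves the
    noiseless outcome by exactly beta times the perturbation, for the
    placebo component and for each drug class."""
    cfg = _single_trial_config(n_active=3, n_placebo=3)
    cohort = s.generate_covariates(cfg, 0)
    bumped = cohort.records.copy()
    bumped[field] += delta
    r0 = s.simulate_outcomes(cohort, cfg, 0).records
    r1 = s.simulate_outcomes(CohortTable(bumped), cfg, 0).records
    diff = (r1["reduction_week6"] - r0["reduction_week6"]).to_numpy()
    expect_p = cfg.beta_placebo[field] * delta
    expect_d = expect_p + cfg.beta_drug["anti_tnf"][field] * delta
    placebo = (r0["arm"] == "placebo").to_numpy()
    assert np.allclose(diff[placebo], expect_p, atol=1e-9)
    assert np.allclose(diff[~placebo], expect_d, atol=1e-9)


def test_simulate_requires_complete_covariates(small_config):
    cohort = s.generate_covariates(small_config, 0)
    df = cohort.records.copy()
    df.loc[0, "crp"] = np.nan
    with pytest.raises(ValueError, match="missing covariates"):
        s.simulate_outcomes(CohortTable(df), small_config, 0)


def test_missingness_zero_rates_identity(small_config):
    cfg = replace(small_config, missing_covariate_rate=0.0,
                  missing_categorical_rate=0.0, missing_week4_rate=0.0,
                  missing_week6_rate=0.0)
    cohort = s.generate_covariates(cfg, 0)
    cohort = s.simulate_outcomes(cohort, cfg, 0)
    out = s.inject_missingness(cohort, cfg, 0)
    pd.testing.assert_frame_equal(cohort.records, out.records)


def test_missingness_rate_one_blanks_every_week6(small_config):
    cfg = replace(small_config, missing_week6_rate=1.0)
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 0), cfg, 0)
    out = s.inject_missingness(cohort, cfg, 0)
    assert out.records["cdai_week6"].isna().all()


def test_missingness_rate_within_binomial_band():
    """A 3% blanking rate on ~10,000 records lands within a 3-SE
    binomial band of 3% for each continuous covariate."""
    cfg = make_small_config(n_active=1100, n_placebo=560,
                            missing_covariate_rate=0.03)
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 0), cfg, 0)
    out = s.inject_missingness(cohort, cfg, 0)
    n = len(out)
    band = 3 * np.sqrt(0.03 * 0.97 / n)
    for col in ("age", "bmi", "baseline_cdai", "crp"):
        assert abs(out.records[col].isna().mean() - 0.03) < band


def test_unrecorded_tnf_history_blanked_wholesale(small_config):
    trial0 = replace(small_config.trials[0], tnf_history_recorded=False)
    cfg = replace(small_config, trials=(trial0,) + small_config.trials[1:])
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 0), cfg, 0)
    out = s.inject_missingness(cohort, cfg, 0).records
    in_t0 = out["trial_id"] == trial0.trial_id
    assert out.loc[in_t0, "tnf_history"].isna().all()
    assert not out.loc[~in_t0, "tnf_history"].isna().all()


@pytest.mark.parametrize("overrides", [
    dict(sigma_placebo=-1.0),
    dict(missing_week6_rate=1.5),
])
def test_invalid_config_rejected(small_config, overrides):
    with pytest.raises(ConfigError):
        replace(small_config, **overrides)


def test_invalid_trial_rejected(small_config):
    bad = replace(small_config.trials[0], p_female=1.2)
    with pytest.raises(ConfigError):
        replace(small_config, trials=(bad,) + small_config.trials[1:])


def test_config_json_round_trip(tmp_path, small_config):
    path = tmp_path / "cfg.json"
    small_config.to_json(path)
    back = GeneratorConfig.from_json(path)
    assert back == small_config
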