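"""Sequential mixed-model fitting, prediction, residualization, tests."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import srsmeta as s
from srsmeta.constants import DRUG_TERMS, PLACEBO_TERMS
from srsmeta.engine import (RankDeficientError, SingleTrialError, _fit_lmm,
                            _pooled_centers)
from srsmeta.schema import CohortTable
from tests.conftest import make_small_config


def test_reference_patient_prediction(published_models, reference_patient):
    """The covariate-wise reference patient's placebo-attributable
    reduction equals the published intercept, 74.69 CDAI points."""
    pred = s.predict_placebo(published_models["placebo"], reference_patient)
    assert pred == pytest.approx(74.69, abs=1e-9)


def test_prediction_is_exactly_linear(published_models, reference_patient):
    m = published_models["placebo"]
    for term in ("age", "bmi", "crp", "baseline_cdai"):
        bumped = dict(reference_patient)
        bumped[term] += 10.0
        slope = (m.predict(bumped) - m.predict(reference_patient)) / 10.0
        assert slope == pytest.approx(m.beta[term], abs=1e-10)
    male = dict(reference_patient, sex="male")
    assert m.predict(male) - m.predict(reference_patient) == \
        pytest.approx(m.beta["sex_male"], abs=1e-10)


def test_prediction_missing_covariate_names_field(published_models,
                                                  reference_patient):
    rec = dict(reference_patient)
    del rec["crp"]
    with pytest.raises(ValueError, match="crp"):
        published_models["placebo"].predict(rec)


def test_fitted_models_store_centers(default_models):
    placebo, drugs, _ = default_models
    assert set(placebo.centers) == {"year", "baseline_cdai", "age", "bmi",
                                    "crp"}
    for m in drugs.values():
        assert "year" not in m.centers
        assert tuple(m.terms) == DRUG_TERMS


def test_single_trial_random_intercept_inestimable(small_cohort):
    one_trial = small_cohort.subset(
        small_cohort.records["trial_id"]
        == small_cohort.records["trial_id"].iloc[0])
    # keep only the placebo arm of a single trial
    with pytest.raises((SingleTrialError, ValueError)):
        s.fit_placebo_model(one_trial)


def test_rank_deficient_design_names_terms(small_cohort):
    df = small_cohort.records.copy()
    df["steroid"] = False  # all-zero column, collinear by degeneracy
    df = df[(df["arm"] == "placebo") & df["reduction_week6"].notna()]
    df = df.reset_index(drop=True)
    centers = _pooled_centers(df, PLACEBO_TERMS)
    with pytest.raises(RankDeficientError, match="steroid"):
        _fit_lmm(df, PLACEBO_TERMS, centers, "placebo")


def test_trial_relabeling_leaves_fixed_effects_unchanged(small_cohort):
    placebo_a = s.fit_placebo_model(small_cohort)
    renamed = small_cohort.records.copy()
    renamed["trial_id"] = "Z_" + renamed["trial_id"]
    placebo_b = s.fit_placebo_model(CohortTable(renamed))
    for t in placebo_a.terms:
        assert placebo_b.beta[t] == pytest.approx(placebo_a.beta[t],
                                                  abs=1e-6)


def test_residualize_conserves_outcome(default_cohort, default_models):
    placebo, _, resid = default_models
    r = resid.records
    np.testing.assert_allclose(
        (r["drug_attributable"] + r["placebo_hat"]).to_numpy(),
        r["reduction_week6"].to_numpy(), rtol=1e-12)
    assert (r["arm"] != "placebo").all()


def test_residualize_unbiased_under_zero_drug_effect():
    """With all drug-class coefficients zero, the mean drug-attributable
    residual of a synthetic active cohort stays within a 3-SE band of 0."""
    zero = {t: 0.0 for t in DRUG_TERMS}
    cfg = make_small_config(n_active=300, n_placebo=300, sigma_placebo=30.0,
                            sigma_drug={c: 10.0 for c in s.DRUG_CLASSES},
                            tau_placebo=0.0,
                            tau_drug={c: 0.0 for c in s.DRUG_CLASSES},
                            missing_covariate_rate=0.0,
                            missing_categorical_rate=0.0,
                            missing_week4_rate=0.0, missing_week6_rate=0.0)
    cfg = replace(cfg, beta_drug={c: dict(zero) for c in s.DRUG_CLASSES})
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 3), cfg, 3)
    placebo = s.fit_placebo_model(cohort)
    resid = s.residualize(cohort, placebo)
    r = resid.records["drug_attributable"].to_numpy()
    # band includes residual noise and placebo-model estimation error
    se = np.sqrt(r.var() / len(r)
                 + float(placebo.cov[0, 0]))
    assert abs(r.mean()) < 3 * se


def test_wald_zero_estimate_p_one(published_models):
    m = published_models["anti_tnf"]
    m = replace_beta(m, "steroid", 0.0)
    tab = s.wald_tests(m)
    assert tab.loc["steroid", "p"] == pytest.approx(1.0)


def replace_beta(model, term, value):
    import copy
    m = copy.deepcopy(model)
    m.beta[term] = value
    return m


def test_wald_1p96_se_p_005(published_models):
    m = published_models["anti_tnf"]
    se = np.sqrt(m.cov[m.terms.index("steroid"), m.terms.index("steroid")])
    m = replace_beta(m, "steroid", 1.959963984540054 * se)
    tab = s.wald_tests(m)
    assert tab.loc["steroid", "p"] == pytest.approx(0.05, abs=1e-9)


def test_lrt_intercept_only_vs_itself(small_cohort):
    df = small_cohort.records
    pdf = df[(df["arm"] == "placebo")
             & df["reduction_week6"].notna()].reset_index(drop=True)
    null = _fit_lmm(pdf, ("intercept",), {}, "placebo", reml=False)
    res = s.lrt_vs_intercept(null, pdf)
    assert res["statistic"] == 0.0
    assert res["p_value"] == 1.0
    assert res["df"] == 0


def test_lrt_detects_real_signal(small_cohort):
    placebo = s.fit_placebo_model(small_cohort)
    df = small_cohort.records
    pdf = df[(df["arm"] == "placebo") & df["reduction_week6"].notna()]
    res = s.lrt_vs_intercept(placebo, pdf)
    assert res["df"] == len(PLACEBO_TERMS) - 1
    assert res["p_value"] < 0.05


def test_lrt_row_mismatch_rejected(small_cohort, default_cohort):
    placebo = s.fit_placebo_model(small_cohort)
    with pytest.raises(ValueError, match="rows"):
        s.lrt_vs_intercept(placebo, default_cohort)


def test_variance_partition_near_one_percent():
    """With tau configured so the trial effect carries ~1% of total
    placebo-response variance, the fitted partition lands near 1%
    (many-trial configuration keeps the REML estimate stable)."""
    cfg = make_small_config(n_active=0, n_placebo=120,
                            missing_covariate_rate=0.0,
                            missing_categorical_rate=0.0,
                            missing_week4_rate=0.0, missing_week6_rate=0.0)
    trials = []
    for i in range(40):
        trials.append(replace(cfg.trials[i % 6],
                              trial_id=f"T{i:02d}", n_active=0,
                              n_placebo=120))
    cfg = replace(cfg, trials=tuple(trials))
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 5), cfg, 5)
    m = s.fit_placebo_model(cohort)
    y = cohort.records["reduction_week6"]
    ratio = m.tau_sq / float(y.var())
    assert 0.002 < ratio < 0.03


def test_model_json_round_trip(tmp_path, default_models):
    placebo, _, _ = default_models
    path = tmp_path / "placebo.json"
    placebo.to_json(path)
    back = s.FittedMixedModel.from_json(path)
    assert back.beta == placebo.beta
    np.testing.assert_allclose(back.cov, placebo.cov)
    assert back.centers == placebo.centers
    assert back.tau_sq == placebo.tau_sq


def test_corrupted_model_file(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"name": "placebo"}')
    with pytest.raises(ValueError, match="corrupted"):
        s.FittedMixedModel.from_json(path)


def test_drug_models_cover_all_classes(default_models):
    _, drugs, _ = default_models
    assert set(drugs) == set(s.DRUG_CLASSES)
    for m in drugs.values():
        assert m.method == "reml"
        assert m.sigma_sq > 0
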