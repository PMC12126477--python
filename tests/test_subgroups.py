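"""Counterfactual predictions, pairwise tests, and the preference lattice."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srsmeta as s
from srsmeta.subgroups import (ALL_CONSISTENT_LABELS, CLASS_ORDER,
                               INCONSISTENT, NO_PREFERENCE, PAIRS,
                               Comparison, PredictionSummary, assign_subgroup,
                               pairwise_test, subgroup_census)

F, S, I = (Comparison.FIRST_SUPERIOR, Comparison.SECOND_SUPERIOR,
           Comparison.INDISTINGUISHABLE)


# ---------------------------------------------------------------------------
# prediction summaries
# ---------------------------------------------------------------------------

def test_bootstrap_zero_covariance_is_exact(published_models,
                                            reference_patient):
    m = published_models["anti_tnf"]
    m.cov = np.zeros_like(m.cov)
    summ = s.bootstrap_prediction(m, reference_patient, 100, seed=0)
    assert summ.se == 0.0
    assert summ.point == pytest.approx(m.predict(reference_patient))


def test_bootstrap_deterministic(published_models, reference_patient):
    m = published_models["anti_integrin"]
    a = s.bootstrap_prediction(m, reference_patient, 500, seed=42)
    b = s.bootstrap_prediction(m, reference_patient, 500, seed=42)
    assert (a.point, a.se) == (b.point, b.se)
    c = s.bootstrap_prediction(m, reference_patient, 500, seed=43)
    assert (a.point, a.se) != (c.point, c.se)


def test_bootstrap_matches_analytic_se(published_models, reference_patient):
    """Oracle equivalence: at 10,000 draws the bootstrap SD agrees with
    the closed form sqrt(x' V x) within 5%."""
    rec = dict(reference_patient, age=55.0, crp=40.0, tnf_history=True)
    for m in published_models.values():
        boot = s.bootstrap_prediction(m, rec, 10_000, seed=1)
        exact = s.analytic_se(m, rec)
        assert boot.se == pytest.approx(exact, rel=0.05)
        assert boot.point == pytest.approx(m.predict(rec),
                                           abs=4 * exact / np.sqrt(10_000) + 1e-9)


def test_bootstrap_converges_to_analytic(published_models,
                                         reference_patient):
    m = published_models["anti_il1223"]
    boot = s.bootstrap_prediction(m, reference_patient, 100_000, seed=2)
    assert boot.se == pytest.approx(s.analytic_se(m, reference_patient),
                                    rel=0.02)
    assert boot.point == pytest.approx(m.predict(reference_patient), rel=0.05)


def test_analytic_se_homogeneity(published_models, reference_patient):
    m = published_models["anti_tnf"]
    base = s.analytic_se(m, reference_patient)
    m.cov = 4.0 * m.cov
    assert s.analytic_se(m, reference_patient) == pytest.approx(2 * base)


def test_non_psd_covariance_rejected(published_models, reference_patient):
    m = published_models["anti_tnf"]
    m.cov = -np.eye(len(m.terms))
    with pytest.raises((ValueError, np.linalg.LinAlgError)):
        s.bootstrap_prediction(m, reference_patient, 100, seed=0)


# ---------------------------------------------------------------------------
# pairwise testing
# ---------------------------------------------------------------------------

def _summ(cls, point, se):
    return PredictionSummary(cls, point, se, 10, "parametric_bootstrap")


def test_identical_summaries_indistinguishable():
    a = _summ("anti_tnf", 50.0, 5.0)
    out, p = pairwise_test(a, _summ("anti_il1223", 50.0, 5.0))
    assert out is I and p == pytest.approx(1.0)


def test_pairwise_z_arithmetic():
    # 40-point gap with SEs of 5 each: z = 40 / sqrt(50) ~ 5.66
    out, p = pairwise_test(_summ("a", 90.0, 5.0), _summ("b", 50.0, 5.0))
    assert out is F
    assert p == pytest.approx(1.5417e-8, rel=0.01)


def test_exact_tie_with_zero_se():
    out, p = pairwise_test(_summ("a", 10.0, 0.0), _summ("b", 10.0, 0.0))
    assert out is I and p == 1.0
    out, _ = pairwise_test(_summ("a", 11.0, 0.0), _summ("b", 10.0, 0.0))
    assert out is F


@settings(deadline=None, derandomize=True, max_examples=100)
@given(pa=st.floats(-100, 100), pb=st.floats(-100, 100),
       sa=st.floats(0, 30), sb=st.floats(0, 30))
def test_pairwise_antisymmetry(pa, pb, sa, sb):
    o1, p1 = pairwise_test(_summ("a", pa, sa), _summ("b", pb, sb))
    o2, p2 = pairwise_test(_summ("b", pb, sb), _summ("a", pa, sa))
    assert p1 == p2
    flip = {F: S, S: F, I: I}
    assert o2 is flip[o1]


# ---------------------------------------------------------------------------
# the lattice
# ---------------------------------------------------------------------------

def test_lattice_total_over_27_triples():
    labels = [assign_subgroup(t).label
              for t in itertools.product([F, S, I], repeat=3)]
    assert len(labels) == 27
    consistent = [l for l in labels if l != INCONSISTENT]
    assert len(consistent) == 13  # the 13 weak orderings of 3 items
    assert len(set(consistent)) == 13


def test_published_categories_reproduced():
    """The seven published preference categories arise from their
    defining pairwise triples (pair order TNF/IL, TNF/INT, IL/INT)."""
    cases = {
        (F, F, I): "TNF > (IL = INT)",
        (F, F, S): "TNF > INT > IL",
        (I, F, F): "(IL = TNF) > INT",
        (S, I, F): "IL > (TNF = INT)",
        (S, F, F): "IL > TNF > INT",
        (F, I, S): "(TNF = INT) > IL",
        (I, I, I): NO_PREFERENCE,
    }
    for triple, label in cases.items():
        pat = assign_subgroup(triple)
        assert pat.label == label
        assert pat.consistent


def test_cyclic_triples_inconsistent():
    # TNF>IL, IL>INT, INT>TNF is a strict cycle
    pat = assign_subgroup((F, S, F))
    assert pat.label == INCONSISTENT
    assert pat.top_tier == frozenset()


def test_no_preference_iff_all_indistinguishable():
    for triple in itertools.product([F, S, I], repeat=3):
        pat = assign_subgroup(triple)
        assert (pat.label == NO_PREFERENCE) == (triple == (I, I, I))


def test_top_tier_nonempty_for_consistent():
    for triple in itertools.product([F, S, I], repeat=3):
        pat = assign_subgroup(triple)
        if pat.consistent:
            assert len(pat.top_tier) >= 1


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def test_census_reproduces_published_aggregates():
    """Weighted by the published subgroup counts, anti-TNF is best or
    tied-for-best for 2418 patients and anti-IL-12/23 strictly best
    for 139."""
    counts = dict(s.published_constants().subgroup_table)
    cen = subgroup_census(counts)
    assert cen["total"] == 5703
    assert cen["best_or_tied"]["anti_tnf"] == 2418
    assert cen["strictly_best"]["anti_il1223"] == 139


def test_census_empty_input():
    cen = subgroup_census([])
    assert cen["total"] == 0
    assert all(v == 0 for v in cen["best_or_tied"].values())


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from(ALL_CONSISTENT_LABELS + [INCONSISTENT]),
                max_size=60))
def test_census_partitions_any_input(labels):
    cen = subgroup_census(labels)
    assert cen["total"] == len(labels)
    assert sum(cen["counts"].values()) == len(labels)


# ---------------------------------------------------------------------------
# whole-cohort assignment
# ---------------------------------------------------------------------------

def test_identical_models_give_no_preference(default_cohort,
                                             published_models):
    tnf = published_models["anti_tnf"]
    models = {cls: tnf for cls in CLASS_ORDER}
    sub = default_cohort.subset(default_cohort.records.index < 50)
    tab = s.assign_all(sub, models, n_draws=200, seed=0, method="analytic")
    assert (tab["label"] == NO_PREFERENCE).all()


def test_assignment_partitions_cohort(default_cohort, default_models):
    _, drugs, _ = default_models
    sub = default_cohort.subset(default_cohort.records.index < 400)
    tab = s.assign_all(sub, drugs, n_draws=300, seed=1)
    assert len(tab) == 400
    cen = subgroup_census(list(tab["label"]))
    assert cen["total"] == 400


def test_assignment_reproducible(default_cohort, default_models):
    _, drugs, _ = default_models
    sub = default_cohort.subset(default_cohort.records.index < 60)
    a = s.assign_all(sub, drugs, n_draws=300, seed=9)
    b = s.assign_all(sub, drugs, n_draws=300, seed=9)
    assert a.equals(b)


def test_shrinking_alpha_grows_no_preference(default_cohort,
                                             default_models):
    """Monotonicity in alpha: every patient with no preference at
    alpha = 0.05 still has none at alpha = 0.005."""
    _, drugs, _ = default_models
    sub = default_cohort.subset(default_cohort.records.index < 300)
    loose = s.assign_all(sub, drugs, alpha=0.05, seed=2, method="analytic")
    strict = s.assign_all(sub, drugs, alpha=0.005, seed=2, method="analytic")
    np_loose = set(loose.loc[loose["label"] == NO_PREFERENCE,
                             "participant_id"])
    np_strict = set(strict.loc[strict["label"] == NO_PREFERENCE,
                               "participant_id"])
    assert np_loose <= np_strict


def test_il_preferring_patients_are_older():
    """Under the published coefficient structure the anti-IL model is
    the only one without a negative age slope, so patients assigned
    IL-strictly-best run older than the cohort average."""
    from dataclasses import replace as dc_replace
    from srsmeta.experiments import scaled_config
    cfg = scaled_config(s.default_config(4), 6000)
    cohort = s.simulate_outcomes(s.generate_covariates(cfg, 4), cfg, 4)
    cohort, _ = s.harmonize(cohort)
    _, drugs, _ = s.fit_all(cohort)
    tab = s.assign_all(cohort, drugs, method="analytic", seed=4)
    merged = tab.merge(cohort.records, on="participant_id")
    il_best = merged["label"].str.startswith("IL >")
    assert il_best.sum() > 0
    assert merged.loc[il_best, "age"].mean() > merged["age"].mean()
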