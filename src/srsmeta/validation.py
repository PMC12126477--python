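"""Subgroup validation: cross-validation, concordance, ablation, and a
pluggable predictor contract for alternative model families.

Concordance between two assignment runs is 1 minus the fraction of
patients with a *contradictory* assignment: some pair of drug classes
strictly reversed between the runs.  A superiority in one run that is
merely indistinguishable in the other reflects lost power, not a
contradiction, and is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from . import engine
from .engine import fit_drug_models, fit_placebo_model, residualize
from .schema import CLASS_TAGS, DRUG_CLASSES, PLACEBO, CohortTable
from .subgroups import (CLASS_ORDER, PAIRS, Comparison, PredictionSummary,
                        assign_all, assign_subgroup, pairwise_test)

_PAIR_COLS = [f"cmp_{CLASS_TAGS[x].lower()}_{CLASS_TAGS[y].lower()}"
              for x, y in PAIRS]


class FoldStarvationError(ValueError):
    """A CV training split lost all trials of some model; use
    trial-stratified folds."""


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    n_contradictory: int

    @property
    def concordance(self) -> float:
        return 1.0 - self.n_contradictory / self.n if self.n else 1.0


def concordance(assign_a: pd.DataFrame,
                assign_b: pd.DataFrame) -> ConcordanceResult:
    """Compare two assignment tables patient-by-patient.

    Both tables must cover the same participant ids (any order).
    """
    a = assign_a.set_index("participant_id")
    b = assign_b.set_index("participant_id")
    if set(a.index) != set(b.index):
        raise ValueError("assignment tables cover different patients")
    b = b.loc[a.index]
    contradictory = np.zeros(len(a), dtype=bool)
    first, second = (Comparison.FIRST_SUPERIOR.value,
                     Comparison.SECOND_SUPERIOR.value)
    for col in _PAIR_COLS:
        ca, cb = a[col].to_numpy(), b[col].to_numpy()
        contradictory |= ((ca == first) & (cb == second)) | \
                         ((ca == second) & (cb == first))
    return ConcordanceResult(n=len(a), n_contradictory=int(contradictory.sum()))


# ---------------------------------------------------------------------------
# cross-validated subgroup rediscovery
# ---------------------------------------------------------------------------

def _stratified_folds(df: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """Fold labels, randomized within trial so every training split
    keeps all trials (random-intercept estimability)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    folds = np.empty(len(df), dtype=int)
    for _, idx in df.groupby("trial_id").indices.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


def crossvalidate_subgroups(cohort: CohortTable, k: int = 10, *,
                            n_draws: int = 1000, alpha: float = 0.05,
                            seed: int = 0,
                            method: str = "analytic") -> dict:
    """Refit the full sequential pipeline on k-1 folds and assign the
    held-out fold, for each fold.

    Returns per-fold assignment tables, per-label fold frequencies, and
    per-label covariate summaries of the assigned patients.  Folds are
    participant-level but stratified by trial; centering constants are
    recomputed from each fold's training sample.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = cohort.records.reset_index(drop=True)
    folds = _stratified_folds(df, k, seed)
    fold_tables: list[pd.DataFrame] = []
    for fold in range(k):
        train = CohortTable(df[folds != fold].reset_index(drop=True))
        test = CohortTable(df[folds == fold].reset_index(drop=True))
        tr = train.records
        if tr[tr["arm"] == PLACEBO]["trial_id"].nunique() < 2:
            raise FoldStarvationError(
                f"fold {fold}: training split has <2 placebo trials; "
                "use trial-stratified folds")
        for cls in DRUG_CLASSES:
            if tr[tr["arm"] == cls]["trial_id"].nunique() < 1:
                raise FoldStarvationError(
                    f"fold {fold}: training split starves drug class {cls}")
        placebo = fit_placebo_model(train)
        resid = residualize(train, placebo)
        drugs = fit_drug_models(resid)
        table = assign_all(test, drugs, n_draws=n_draws, alpha=alpha,
                           seed=seed * 1000 + fold, method=method)
        table.insert(0, "fold", fold)
        fold_tables.append(table)
    combined = pd.concat(fold_tables, ignore_index=True)
    label_by_fold = (combined.groupby(["fold", "label"]).size()
                     .unstack(fill_value=0))
    merged = combined.merge(df, on="participant_id")
    covars = (merged.groupby("label")[["age", "baseline_cdai", "crp", "bmi"]]
              .mean())
    covars["p_female"] = (merged.assign(f=merged["sex"] == "female")
                          .groupby("label")["f"].mean())
    return {"folds": fold_tables, "assignments": combined,
            "label_by_fold": label_by_fold,
            "label_covariates": covars}


# ---------------------------------------------------------------------------
# covariate ablation
# ---------------------------------------------------------------------------

def _refit_without(cohort: CohortTable, drop_term: str):
    """Sequential fit with one fixed-effect term removed everywhere."""
    from .constants import DRUG_TERMS, PLACEBO_TERMS
    if drop_term not in DRUG_TERMS:
        raise ValueError(f"unknown model term {drop_term!r}")
    p_terms = tuple(t for t in PLACEBO_TERMS if t != drop_term)
    d_terms = tuple(t for t in DRUG_TERMS if t != drop_term)

    df = cohort.records
    pdf = df[(df["arm"] == PLACEBO)
             & df["reduction_week6"].notna()].reset_index(drop=True)
    centers = engine._pooled_centers(pdf, p_terms)
    placebo = engine._fit_lmm(pdf, p_terms, centers, PLACEBO)
    resid = residualize(cohort, placebo)
    drugs = {}
    for cls in DRUG_CLASSES:
        sub = resid.records[resid.records["arm"] == cls].reset_index(drop=True)
        if len(sub) == 0:
            continue
        sub = sub.copy()
        sub["reduction_week6"] = sub["drug_attributable"]
        centers = engine._pooled_centers(sub, d_terms)
        drugs[cls] = engine._fit_lmm(sub, d_terms, centers, cls)
    return placebo, drugs


def ablate_and_compare(cohort: CohortTable, variables: list[str], *,
                       n_draws: int = 1000, alpha: float = 0.05,
                       seed: int = 0, method: str = "analytic"
                       ) -> dict[str, ConcordanceResult]:
    """Drop each variable (one at a time) from all four models, rerun
    fitting and assignment, and report concordance with the full run."""
    if isinstance(variables, str):
        raise TypeError("pass a list of variable names")
    _, full_drugs, _ = engine.fit_all(cohort)
    full = assign_all(cohort, full_drugs, n_draws=n_draws, alpha=alpha,
                      seed=seed, method=method)
    out = {}
    for var in variables:
        _, drugs = _refit_without(cohort, var)
        ablated = assign_all(cohort, drugs, n_draws=n_draws, alpha=alpha,
                             seed=seed, method=method)
        out[var] = concordance(full, ablated)
    return out


# ---------------------------------------------------------------------------
# pluggable predictor families
# ---------------------------------------------------------------------------

@runtime_checkable
class PredictorContract(Protocol):
    """Contract an alternative model family must satisfy to stand in
    for the linear mixed models in subgroup assignment."""

    def fit(self, df: pd.DataFrame, outcome: str) -> "PredictorContract": ...

    def predict(self, df: pd.DataFrame) -> np.ndarray: ...

    def predict_uncertainty(self, df: pd.DataFrame, n_draws: int,
                            seed: int) -> tuple[np.ndarray, np.ndarray]: ...


class ResamplingPredictor:
    """Wrap any sklearn-style regressor factory in the contract.

    Uncertainty comes from bootstrap resampling: the training rows are
    resampled with replacement ``n_boot`` times, the regressor refit on
    each resample, and a patient's prediction summarised as the median
    (point) and SD (se) over the refits.
    """

    def __init__(self, factory: Callable, n_boot: int = 100,
                 features: tuple[str, ...] = ("baseline_cdai", "age", "bmi",
                                              "crp", "tnf_history", "steroid",
                                              "immunomod", "ileal",
                                              "sex_male")):
        self.factory = factory
        self.n_boot = n_boot
        self.features = features
        self._fits = None
        self._full_fit = None

    def _X(self, df: pd.DataFrame) -> np.ndarray:
        d = df.copy()
        if "sex_male" not in d.columns:
            d["sex_male"] = (d["sex"] == "male").astype(float)
        return d[list(self.features)].astype(float).to_numpy()

    def fit(self, df: pd.DataFrame, outcome: str) -> "ResamplingPredictor":
        X, y = self._X(df), df[outcome].to_numpy(dtype=float)
        self._full_fit = self.factory().fit(X, y)
        self._train = (X, y)
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self._full_fit.predict(self._X(df))

    def predict_uncertainty(self, df: pd.DataFrame, n_draws: int = 100,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        X, y = self._train
        n_boot = min(n_draws, self.n_boot) if n_draws else self.n_boot
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
        Xq = self._X(df)
        preds = np.empty((n_boot, len(df)))
        for b in range(n_boot):
            idx = rng.integers(0, len(y), len(y))
            preds[b] = self.factory().fit(X[idx], y[idx]).predict(Xq)
        return np.median(preds, axis=0), np.std(preds, axis=0, ddof=1)


def assign_with_family(cohort: CohortTable,
                       predictor_factory: Callable[[], PredictorContract],
                       *, n_draws: int = 100, alpha: float = 0.05,
                       seed: int = 0) -> pd.DataFrame:
    """Run the full sequential workflow with an alternative predictor
    family: fit a placebo predictor, residualize, fit one predictor per
    drug class on the residuals, and assign every participant by
    pairwise testing of the bootstrap summaries."""
    df = cohort.records.reset_index(drop=True)
    pdf = df[(df["arm"] == PLACEBO) & df["reduction_week6"].notna()]
    placebo = predictor_factory().fit(pdf, "reduction_week6")
    active = df[(df["arm"] != PLACEBO)
                & df["reduction_week6"].notna()].copy()
    active["drug_attributable"] = (active["reduction_week6"].to_numpy()
                                   - placebo.predict(active))
    class_fits = {}
    for ci, cls in enumerate(CLASS_ORDER):
        sub = active[active["arm"] == cls]
        class_fits[cls] = predictor_factory().fit(sub, "drug_attributable")
    cols = {"participant_id": df["participant_id"]}
    summ = {}
    for ci, cls in enumerate(CLASS_ORDER):
        pts, ses = class_fits[cls].predict_uncertainty(df, n_draws,
                                                       seed * 10 + ci)
        summ[cls] = (pts, ses)
        tag = CLASS_TAGS[cls].lower()
        cols[f"point_{tag}"], cols[f"se_{tag}"] = pts, ses
    out = pd.DataFrame(cols)
    labels = []
    pair_vals = {c: [] for c in _PAIR_COLS}
    for i in range(len(df)):
        outcomes = []
        for (x, y), col in zip(PAIRS, _PAIR_COLS):
            sx = PredictionSummary(x, summ[x][0][i], summ[x][1][i],
                                   max(n_draws, 1), "parametric_bootstrap")
            sy = PredictionSummary(y, summ[y][0][i], summ[y][1][i],
                                   max(n_draws, 1), "parametric_bootstrap")
            cmp_, _ = pairwise_test(sx, sy, alpha)
            outcomes.append(cmp_)
            pair_vals[col].append(cmp_.value)
        labels.append(assign_subgroup(outcomes).label)
    for col, vals in pair_vals.items():
        out[col] = vals
    out["label"] = labels
    return out


def compare_predictor_families(cohort: CohortTable,
                               predictor_factory: Callable[[], PredictorContract],
                               *, n_draws: int = 100, alpha: float = 0.05,
                               seed: int = 0,
                               baseline: pd.DataFrame | None = None
                               ) -> ConcordanceResult:
    """Concordance of an alternative family's subgroup assignments with
    the linear mixed-model pipeline's (``baseline``, computed here when
    not supplied)."""
    if baseline is None:
        _, drugs, _ = engine.fit_all(cohort)
        baseline = assign_all(cohort, drugs, n_draws=n_draws, alpha=alpha,
                              seed=seed, method="analytic")
    alt = assign_with_family(cohort, predictor_factory, n_draws=n_draws,
                             alpha=alpha, seed=seed)
    return concordance(baseline, alt)
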