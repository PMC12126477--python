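"""Per-patient treatment recommendation.

Reproduces the decision-support rules of the interactive dashboard the
models were built for: every input except the baseline CDAI is
mandatory; a missing CDAI is imputed as 300 (moderate-to-severe
disease) and a missing CRP as the pooled-population median; the three
drug-class models are compared pairwise (analytic standard errors by
default, for real-time use) and the resulting preference pattern is
rendered as a one-line narrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import FittedMixedModel
from .schema import CDAI_ELIGIBILITY, CLASS_TAGS, CohortTable
from .subgroups import (CLASS_ORDER, NO_PREFERENCE, PAIRS, PredictionSummary,
                        analytic_prediction, assign_subgroup,
                        bootstrap_prediction, pairwise_test)

DEFAULT_CDAI = 300.0  # moderate-to-severe disease

MANDATORY_FIELDS = ("age", "sex", "bmi", "crp", "steroid", "immunomod",
                    "tnf_history", "ileal")
#: mandatory fields that may nevertheless be left blank because a
#: documented imputation default exists
_IMPUTABLE = ("crp",)


class MissingInputError(ValueError):
    """A mandatory patient field was left blank."""


@dataclass(frozen=True)
class PatientInput:
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    crp: float | None = None
    steroid: bool | None = None
    immunomod: bool | None = None
    tnf_history: bool | None = None
    ileal: bool | None = None
    baseline_cdai: float | None = None  # optional

    def as_record(self) -> dict:
        d = {f: getattr(self, f) for f in MANDATORY_FIELDS}
        d["baseline_cdai"] = self.baseline_cdai
        d["sex_male"] = 1.0 if self.sex == "male" else 0.0
        return d


@dataclass(frozen=True)
class Recommendation:
    predictions: dict
    pairwise: dict
    label: str
    top_tier: frozenset
    narrative: str
    warnings: tuple = ()


def pooled_crp_median(reference: CohortTable) -> float:
    """Median CRP of the pooled reference population (mg/L)."""
    return float(reference.records["crp"].median())


def prepare_input(raw: PatientInput,
                  reference_crp_median: float) -> PatientInput:
    """Apply the imputation defaults and enforce mandatory fields.

    Never overrides a supplied value.  Raises
    :class:`MissingInputError` naming the first missing mandatory
    field.
    """
    for f in MANDATORY_FIELDS:
        if f not in _IMPUTABLE and getattr(raw, f) is None:
            raise MissingInputError(
                f"mandatory input {f!r} is missing; enter 0 for numeric or "
                "'no' for yes/no fields if unknown")
    out = raw
    if out.crp is None:
        out = replace(out, crp=reference_crp_median)
    if out.baseline_cdai is None:
        out = replace(out, baseline_cdai=DEFAULT_CDAI)
    if not 0.0 <= out.baseline_cdai <= 600.0:
        raise ValueError(f"baseline CDAI {out.baseline_cdai} outside the "
                         "sanity range [0, 600]")
    return out


_FULL_NAMES = {"TNF": "anti-TNF", "IL": "anti-IL-12/23",
               "INT": "anti-integrin"}


def _narrative(label: str, top_tier) -> str:
    if label == NO_PREFERENCE:
        return ("No drug class shows statistically distinguishable "
                "superiority for this patient.")
    if label == "inconsistent":
        return ("Pairwise comparisons are mutually inconsistent; no ordered "
                "recommendation can be made.")
    names = sorted(_FULL_NAMES[CLASS_TAGS[c]] for c in top_tier)
    if len(names) == 1:
        return (f"Predicted drug-attributable benefit is greatest with the "
                f"{names[0]} class.")
    return (f"{' and '.join(names)} are statistically indistinguishable "
            "and preferred over the remaining class.")


def _eligibility_warnings(patient: PatientInput) -> list[str]:
    w = []
    lo, hi = CDAI_ELIGIBILITY
    if not lo <= patient.baseline_cdai <= hi:
        w.append(f"baseline CDAI {patient.baseline_cdai:g} outside the "
                 f"trial eligibility window [{lo:g}, {hi:g}]")
    if patient.age is not None and not 18 <= patient.age <= 90:
        w.append(f"age {patient.age:g} outside the modeled range [18, 90]")
    if patient.crp is not None and patient.crp < 0:
        w.append("negative CRP")
    return w


def recommend(patient: PatientInput, models: dict[str, FittedMixedModel],
              mode: str = "analytic", alpha: float = 0.05,
              n_draws: int = 10_000, seed: int = 0) -> Recommendation:
    """Pairwise-compare the three drug-class predictions for one
    patient and return the labeled recommendation.

    ``mode`` selects analytic (closed-form, deterministic) or
    parametric-bootstrap standard errors.
    """
    if mode not in ("analytic", "bootstrap"):
        raise ValueError("mode must be 'analytic' or 'bootstrap'")
    record = patient.as_record()
    preds: dict[str, PredictionSummary] = {}
    for ci, cls in enumerate(CLASS_ORDER):
        if mode == "analytic":
            preds[cls] = analytic_prediction(models[cls], record)
        else:
            preds[cls] = bootstrap_prediction(
                models[cls], record, n_draws,
                np.random.SeedSequence([seed, ci]))
    outcomes, pairwise = [], {}
    for x, y in PAIRS:
        cmp_, p = pairwise_test(preds[x], preds[y], alpha)
        outcomes.append(cmp_)
        pairwise[(x, y)] = (cmp_, p)
    pattern = assign_subgroup(outcomes)
    return Recommendation(
        predictions=preds, pairwise=pairwise, label=pattern.label,
        top_tier=pattern.top_tier,
        narrative=_narrative(pattern.label, pattern.top_tier),
        warnings=tuple(_eligibility_warnings(patient)))


def load_omop_patient(person_csv, measurement_csv=None,
                      drug_exposure_csv=None) -> PatientInput:
    """Minimal reader for an OMOP-shaped CSV export.

    Expects a one-row ``person`` table with ``year_of_birth`` and
    ``gender`` columns and optional measurement (``field,value``) and
    drug-exposure (``drug_name``) tables.  This is a stub input path
    for piping EHR extracts into :func:`recommend`; full OMOP
    connectivity is out of scope.
    """
    import datetime
    person = pd.read_csv(person_csv)
    if len(person) != 1:
        raise ValueError("person table must contain exactly one row")
    row = person.iloc[0]
    age = datetime.date.today().year - int(row["year_of_birth"])
    sex = str(row["gender"]).strip().lower()
    sex = {"f": "female", "m": "male"}.get(sex, sex)
    fields: dict = {"age": float(age), "sex": sex}
    if measurement_csv is not None:
        meas = pd.read_csv(measurement_csv)
        for _, m in meas.iterrows():
            f = str(m["field"])
            if f in ("bmi", "crp", "baseline_cdai"):
                fields[f] = float(m["value"])
    if drug_exposure_csv is not None:
        drugs = pd.read_csv(drug_exposure_csv)
        names = set(drugs["drug_name"].astype(str).str.lower())
        anti_tnfs = {"infliximab", "adalimumab", "certolizumab",
                     "certolizumab pegol"}
        fields["tnf_history"] = bool(names & anti_tnfs)
        fields["steroid"] = bool(names & {"prednisone", "budesonide",
                                          "methylprednisolone"})
        fields["immunomod"] = bool(names & {"azathioprine", "methotrexate",
                                            "mercaptopurine"})
    return PatientInput(**fields)
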