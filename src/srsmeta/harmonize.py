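"""Quality-control and imputation rules for a raw pooled cohort.

Continuous covariates get pooled-median imputation; records missing any
boolean covariate are dropped; the week-6 outcome is computed directly
when the week-6 CDAI is present and otherwise carried forward from
week 4 (LOCF); early anti-TNF trials that never recorded prior-exposure
history get that flag imputed deterministically to "no prior use".

Order matters and is fixed by :func:`harmonize`:
deterministic anti-TNF-history imputation first (so those records are
not swept up by the categorical-drop rule), then median imputation and
the categorical drop, then LOCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .schema import (BOOLEAN_COVARIATES, CONTINUOUS_COVARIATES, CohortTable)


class CannotImputeError(ValueError):
    """A continuous field is missing for every record."""


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_dropped_categorical: int = 0
    n_imputed_by_field: dict = field(default_factory=dict)
    n_locf: int = 0
    n_outcome_missing: int = 0
    medians_used: dict = field(default_factory=dict)

    def merged(self, other: "HarmonizationReport") -> "HarmonizationReport":
        merged_counts = dict(self.n_imputed_by_field)
        for k, v in other.n_imputed_by_field.items():
            merged_counts[k] = merged_counts.get(k, 0) + v
        return HarmonizationReport(
            n_input=self.n_input or other.n_input,
            n_dropped_categorical=(self.n_dropped_categorical
                                   + other.n_dropped_categorical),
            n_imputed_by_field=merged_counts,
            n_locf=self.n_locf + other.n_locf,
            n_outcome_missing=self.n_outcome_missing + other.n_outcome_missing,
            medians_used={**self.medians_used, **other.medians_used})

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def impute_tnf_history(cohort: CohortTable,
                       pre_approval_trials: set[str]) -> CohortTable:
    """Set missing anti-TNF history to False for listed trials only.

    Trials conducted before other drugs of the class were available
    excluded previously exposed patients by design, so a missing flag
    there deterministically means "no prior use".
    """
    out = cohort.records.copy()
    mask = (out["trial_id"].isin(pre_approval_trials)
            & out["tnf_history"].isna())
    out.loc[mask, "tnf_history"] = False
    return CohortTable(out, cohort.provenance)


def impute_baseline(cohort: CohortTable
                    ) -> tuple[CohortTable, HarmonizationReport]:
    """Pooled-median imputation for continuous covariates; drop records
    with any missing boolean covariate."""
    df = cohort.records.copy()
    report = HarmonizationReport(n_input=len(df))
    for col in CONTINUOUS_COVARIATES:
        missing = df[col].isna()
        if missing.all():
            raise CannotImputeError(f"all values of {col!r} are missing")
        if missing.any():
            med = float(df.loc[~missing, col].median())
            df.loc[missing, col] = med
            report.n_imputed_by_field[col] = int(missing.sum())
            report.medians_used[col] = med
    drop = df[list(BOOLEAN_COVARIATES)].isna().any(axis=1)
    report.n_dropped_categorical = int(drop.sum())
    df = df.loc[~drop].reset_index(drop=True)
    return CohortTable(df, cohort.provenance), report


def locf_outcome(cohort: CohortTable
                 ) -> tuple[CohortTable, HarmonizationReport]:
    """Compute the week-6 reduction, carrying the week-4 CDAI forward
    when week 6 is missing.

    Records with neither follow-up keep a missing reduction and are
    counted as outcome-missing; model fitting excludes them.
    """
    df = cohort.records.copy()
    if df["baseline_cdai"].isna().any():
        raise ValueError("baseline CDAI must be complete before LOCF; "
                         "run impute_baseline first")
    report = HarmonizationReport(n_input=len(df))
    have6 = df["cdai_week6"].notna()
    have4 = df["cdai_week4"].notna()
    locf = ~have6 & have4
    df.loc[have6, "reduction_week6"] = (df.loc[have6, "baseline_cdai"]
                                        - df.loc[have6, "cdai_week6"])
    df.loc[locf, "reduction_week6"] = (df.loc[locf, "baseline_cdai"]
                                       - df.loc[locf, "cdai_week4"])
    df.loc[~have6 & ~have4, "reduction_week6"] = np.nan
    report.n_locf = int(locf.sum())
    report.n_outcome_missing = int((~have6 & ~have4).sum())
    return CohortTable(df, cohort.provenance), report


def harmonize(cohort: CohortTable,
              pre_approval_trials: set[str] = frozenset()
              ) -> tuple[CohortTable, HarmonizationReport]:
    """Full pipeline: deterministic anti-TNF-history imputation, then
    median imputation + categorical drop, then LOCF.  Idempotent."""
    step1 = impute_tnf_history(cohort, pre_approval_trials)
    step2, rep_a = impute_baseline(step1)
    step3, rep_b = locf_outcome(step2)
    report = rep_a.merged(rep_b)
    report.n_input = len(cohort)
    return step3, report
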