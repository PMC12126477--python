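"""Participant-level data model and CSV I/O.

A cohort is a table with one row per trial participant.  The outcome of
interest is the reduction in the Crohn's Disease Activity Index (CDAI)
six weeks after treatment start, stored positive-for-improvement
(baseline minus follow-up).  Arms are placebo or one of three biologic
drug classes: anti-TNF, anti-IL-12/23, anti-integrin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLACEBO = "placebo"
ANTI_TNF = "anti_tnf"
ANTI_IL1223 = "anti_il1223"
ANTI_INTEGRIN = "anti_integrin"

DRUG_CLASSES = (ANTI_TNF, ANTI_IL1223, ANTI_INTEGRIN)
ARMS = (PLACEBO,) + DRUG_CLASSES

#: short display tags used in preference-pattern labels
CLASS_TAGS = {ANTI_TNF: "TNF", ANTI_IL1223: "IL", ANTI_INTEGRIN: "INT"}

SEXES = ("female", "male")

#: continuous covariates subject to median imputation
CONTINUOUS_COVARIATES = ("age", "bmi", "baseline_cdai", "crp")
#: boolean covariates; a missing value here drops the record
BOOLEAN_COVARIATES = ("tnf_history", "steroid", "immunomod", "ileal")

ID_COLUMNS = ("participant_id", "trial_id")
REQUIRED_COLUMNS = ID_COLUMNS + ("year", "arm", "age", "sex", "bmi",
                                 "baseline_cdai", "crp") + BOOLEAN_COVARIATES
OUTCOME_COLUMNS = ("cdai_week4", "cdai_week6", "reduction_week6")
ALL_COLUMNS = REQUIRED_COLUMNS + OUTCOME_COLUMNS

#: eligibility window for baseline CDAI (moderate-to-severe disease)
CDAI_ELIGIBILITY = (220.0, 450.0)

_TRUE_TOKENS = {"1", "true", "yes", "t", "y"}
_FALSE_TOKENS = {"0", "false", "no", "f", "n"}


class SchemaError(ValueError):
    """Raised when a participant table violates the expected schema."""


class EmptyInputError(ValueError):
    """Raised when a participant table contains no records."""


@dataclass
class CohortTable:
    """An ordered collection of participant records.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per participant, columns per :data:`ALL_COLUMNS`.
    provenance : str
        Free text describing where the table came from (a file path or
        a generator seed/config digest).
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = coerce_schema(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "CohortTable":
        return CohortTable(self.records.copy(), self.provenance)

    def subset(self, mask, provenance: str | None = None) -> "CohortTable":
        return CohortTable(self.records.loc[mask].reset_index(drop=True),
                           provenance if provenance is not None else self.provenance)


def _parse_bool_series(s: pd.Series, name: str, errors: list[str]) -> pd.Series:
    out = pd.array([pd.NA] * len(s), dtype="boolean")
    for i, v in enumerate(s):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            continue
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
            continue
        tok = str(v).strip().lower()
        if tok in ("", "nan", "na"):
            continue
        if tok in _TRUE_TOKENS:
            out[i] = True
        elif tok in _FALSE_TOKENS:
            out[i] = False
        else:
            errors.append(f"row {i}: cannot parse boolean field {name!r} from {v!r}")
    return pd.Series(out, index=s.index, name=name)


def coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw DataFrame to the cohort schema, validating types.

    Raises :class:`SchemaError` listing offending rows on failure.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    errors: list[str] = []
    for col in ("participant_id", "trial_id"):
        df[col] = df[col].astype(str)
    for col in ("year",):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        if df[col].isna().any():
            bad = list(df.index[df[col].isna()][:5])
            errors.append(f"rows {bad}: non-integer year")
    for col in CONTINUOUS_COVARIATES + OUTCOME_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        for i in df.index[newly_bad][:5]:
            errors.append(f"row {i}: cannot parse numeric field {col!r} from {df.at[i, col]!r}")
        df[col] = coerced.astype(float)
    for col in BOOLEAN_COVARIATES:
        df[col] = _parse_bool_series(df[col], col, errors)
    df["arm"] = df["arm"].astype(str)
    bad_arm = ~df["arm"].isin(ARMS)
    for i in df.index[bad_arm][:5]:
        errors.append(f"row {i}: unknown arm {df.at[i, 'arm']!r}")
    df["sex"] = df["sex"].astype(str).str.lower()
    bad_sex = ~df["sex"].isin(SEXES)
    for i in df.index[bad_sex][:5]:
        errors.append(f"row {i}: unknown sex {df.at[i, 'sex']!r}")
    if errors:
        raise SchemaError("; ".join(errors))
    if df["participant_id"].duplicated().any():
        dupes = df["participant_id"][df["participant_id"].duplicated()].head().tolist()
        raise SchemaError(f"duplicate participant_id values: {dupes}")
    return df[list(ALL_COLUMNS)].reset_index(drop=True)


def load_cohort(path) -> CohortTable:
    """Read a participant table from CSV.

    Missing values are empty fields; booleans accept 0/1, yes/no,
    true/false.  Raises :class:`EmptyInputError` for a header-only file
    and :class:`SchemaError` for missing columns or unparseable rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    if len(df) == 0:
        # distinguish "no rows" from "no required columns"
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        raise EmptyInputError(f"{path}: no participant rows")
    return CohortTable(df, provenance=str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as UTF-8 comma-separated text, empty field = missing."""
    df = cohort.records.copy()
    for col in BOOLEAN_COVARIATES:
        df[col] = df[col].map({True: "true", False: "false"}, na_action="ignore")
    df.to_csv(path, index=False, na_rep="")


def cohort_census(cohort: CohortTable) -> pd.DataFrame:
    """Participant counts by trial and arm.

    Returns a trial × arm table of counts whose grand total equals the
    number of records.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cannot take a census of an empty cohort")
    tab = (cohort.records.groupby(["trial_id", "arm"], sort=True)
           .size().unstack(fill_value=0))
    for arm in ARMS:
        if arm not in tab.columns:
            tab[arm] = 0
    return tab[list(ARMS)]


def cohort_digest(df: pd.DataFrame) -> str:
    """Short content hash used to tag generated cohorts."""
    h = hashlib.sha256(pd.util.hash_pandas_object(
        df.astype(str), index=False).values.tobytes())
    return h.hexdigest()[:12]
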