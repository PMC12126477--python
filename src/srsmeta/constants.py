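"""Packaged reference values for the pooled Crohn's disease trial cohort.

These are the published per-trial baseline summaries, the four fitted
mixed-model coefficient sets (one placebo model, three drug-class
models of the residual, drug-attributable CDAI reduction), and the
subgroup counts produced by pairwise preference testing — together with
the analysis constants (alpha, the 100-point clinical-response
threshold, bootstrap draw count, fold count, power-simulation grid).

The synthetic-cohort generator is parameterised from these tables, and
the worked examples/regression tests check predictions against them.
All values are frozen; :func:`published_constants` always returns an
equal-comparing object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .schema import ANTI_IL1223, ANTI_INTEGRIN, ANTI_TNF, PLACEBO

# ---------------------------------------------------------------------------
# Per-trial baseline characteristics (15 induction trials, 1999-2015).
# Continuous covariates as (mean, sd); binary covariates as proportion.
# Trials without a 6-week parallel placebo arm have n_placebo = 0.
# ---------------------------------------------------------------------------

_TRIAL_ROWS = [
    # trial_id, drug_class, year, n_active, n_placebo,
    #   age(m,sd), bmi(m,sd), cdai(m,sd), crp(m,sd),
    #   p_female, p_tnf_history, p_steroid, p_immunomod, p_ileal
    ("CERTIFI", ANTI_IL1223, 2008, 126, 126, (39, 13), (26, 7.3), (320, 67), (21, 28),
     107 / 252, 1.00, 134 / 252, 64 / 252, 182 / 252),
    ("UNITI1", ANTI_IL1223, 2011, 252, 250, (37, 12), (22, 0.58), (320, 60), (18, 23),
     224 / 502, 479 / 502, 232 / 502, 166 / 502, 407 / 502),
    ("UNITI2", ANTI_IL1223, 2011, 209, 207, (39, 13), (25, 6.2), (300, 56), (16, 20),
     189 / 416, 135 / 416, 172 / 416, 143 / 416, 335 / 416),
    ("ENACT", ANTI_INTEGRIN, 2001, 698, 177, (38, 13), (25, 5.6), (300, 61), (19, 25),
     372 / 875, 348 / 875, 356 / 875, 330 / 875, 675 / 875),
    ("GEMINI2", ANTI_INTEGRIN, 2008, 915, 135, (36, 12), (24, 6.0), (320, 69), (21, 26),
     492 / 1050, 649 / 1050, 532 / 1050, 341 / 1050, 752 / 1050),
    ("GEMINI3", ANTI_INTEGRIN, 2010, 205, 202, (38, 13), (24, 5.7), (310, 53), (18, 22),
     176 / 407, 306 / 407, 213 / 407, 137 / 407, 310 / 407),
    ("ACCENT", ANTI_TNF, 1999, 190, 0, (37, 12), (24, 4.7), (310, 54), (20, 23),
     79 / 190, 0.00, 94 / 190, 44 / 190, 155 / 190),
    ("CLASSIC", ANTI_TNF, 2002, 73, 0, (38, 11), (26, 6.0), (290, 52), (13, 18),
     35 / 73, 2 / 73, 21 / 73, 19 / 73, 47 / 73),
    ("EXTEND", ANTI_TNF, 2006, 64, 0, (37, 11), (25, 4.6), (320, 69), (20, 21),
     24 / 64, 31 / 64, 6 / 64, 26 / 64, 48 / 64),
    ("NCT00348283", ANTI_TNF, 2006, 30, 30, (33, 12), (20, 2.7), (290, 58), (31, 21),
     47 / 60, 1 / 60, 14 / 60, 17 / 60, 42 / 60),
    ("NCT00291668", ANTI_TNF, 2008, 210, 199, (37, 12), (24, 4.9), (290, 60), (19, 26),
     181 / 409, 0.00, 179 / 409, 139 / 409, 286 / 409),
    ("NCT02499783", ANTI_TNF, 2015, 102, 0, (33, 10), (19, 2.7), (270, 48), (24, 25),
     67 / 102, 0.00, 31 / 102, 61 / 102, 82 / 102),
    ("PRECISE1", ANTI_TNF, 2003, 298, 295, (37, 12), (24, 5.3), (300, 61), (18, 25),
     259 / 593, 161 / 593, 235 / 593, 235 / 593, 425 / 593),
    ("PRECISE2", ANTI_TNF, 2003, 559, 0, (39, 13), (24, 5.1), (300, 59), (20, 28),
     271 / 559, 156 / 559, 205 / 559, 230 / 559, 378 / 559),
    ("SONIC", ANTI_TNF, 2005, 151, 0, (36, 13), (25, 5.5), (290, 62), (25, 28),
     77 / 151, 0.00, 58 / 151, 0.00, 104 / 151),
]

#: anti-TNF trials conducted before/around first-in-class approval that
#: excluded prior-exposure patients and did not record the history flag
PRE_APPROVAL_TRIALS = frozenset({"ACCENT", "PRECISE1", "SONIC"})


@dataclass(frozen=True)
class TrialSummary:
    trial_id: str
    drug_class: str
    year: int
    n_active: int
    n_placebo: int
    age: tuple[float, float]
    bmi: tuple[float, float]
    baseline_cdai: tuple[float, float]
    crp: tuple[float, float]
    p_female: float
    p_tnf_history: float
    p_steroid: float
    p_immunomod: float
    p_ileal: float

    @property
    def n_total(self) -> int:
        return self.n_active + self.n_placebo


TRIAL_TABLE: tuple[TrialSummary, ...] = tuple(TrialSummary(*row) for row in _TRIAL_ROWS)

# ---------------------------------------------------------------------------
# Fixed-effect coefficient sets for the reduction in CDAI at week 6.
# Continuous predictors (year, baseline CDAI, age, BMI, CRP) are centered;
# sex is coded male = 1 (female reference).  The placebo model additionally
# carries the study-year slope; the drug-class models do not (too little
# calendar variation within a class).
# ---------------------------------------------------------------------------

PLACEBO_TERMS = ("intercept", "year", "baseline_cdai", "age", "bmi", "crp",
                 "tnf_history", "sex_male", "steroid", "immunomod", "ileal")
DRUG_TERMS = tuple(t for t in PLACEBO_TERMS if t != "year")


def _coefset(names, est, se) -> Mapping[str, tuple[float, float]]:
    return MappingProxyType({n: (e, s) for n, e, s in zip(names, est, se)})


COEFFICIENT_TABLE: Mapping[str, Mapping[str, tuple[float, float]]] = MappingProxyType({
    PLACEBO: _coefset(
        PLACEBO_TERMS,
        [74.69, -1.96, 0.33, 0.41, 0.72, -0.22, -27.31, 2.22, 0.32, -1.74, 4.88],
        [9.48, 0.99, 0.04, 0.18, 0.43, 0.10, 5.24, 4.42, 4.44, 4.69, 5.05]),
    ANTI_IL1223: _coefset(
        DRUG_TERMS,
        [22.19, -0.03, 0.30, -1.69, 0.48, 28.00, -6.41, 19.82, 0.54, -9.14],
        [22.01, 0.06, 0.30, 0.75, 0.16, 12.06, 7.74, 7.60, 8.28, 9.64]),
    ANTI_INTEGRIN: _coefset(
        DRUG_TERMS,
        [36.82, 0.02, -0.54, -0.35, 0.12, 1.66, -4.03, 4.97, -4.35, -8.15],
        [7.34, 0.04, 0.19, 0.39, 0.09, 4.49, 4.32, 4.32, 4.54, 4.97]),
    ANTI_TNF: _coefset(
        DRUG_TERMS,
        [54.96, 0.11, -1.23, -0.19, 0.35, 7.03, 0.68, -1.69, -1.70, -7.29],
        [9.80, 0.04, 0.18, 0.44, 0.08, 6.09, 4.16, 4.30, 4.55, 4.58]),
})

# ---------------------------------------------------------------------------
# Published subgroup counts from pairwise preference testing on the pooled
# cohort (labels are preference patterns over the three drug classes).
# ---------------------------------------------------------------------------

SUBGROUP_TABLE: Mapping[str, int] = MappingProxyType({
    "TNF > (IL = INT)": 2021,
    "TNF > INT > IL": 43,
    "(IL = TNF) > INT": 354,
    "IL > (TNF = INT)": 138,
    "IL > TNF > INT": 1,
    "(TNF = INT) > IL": 4,
    "no preference": 3142,
})


@dataclass(frozen=True)
class PublishedConstants:
    """Frozen bundle of the published tables and analysis constants."""

    trial_table: tuple[TrialSummary, ...] = TRIAL_TABLE
    coefficient_table: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: COEFFICIENT_TABLE)
    subgroup_table: Mapping[str, int] = field(default_factory=lambda: SUBGROUP_TABLE)
    alpha: float = 0.05
    response_threshold: float = 100.0
    n_bootstrap: int = 10_000
    cv_folds: int = 10
    power_sims: int = 1000
    power_arm_sizes: tuple[int, ...] = (100, 250, 500)

    def coefficients(self, model: str) -> dict[str, float]:
        """Point estimates for one model, term -> CDAI points per unit."""
        return {term: est for term, (est, _) in self.coefficient_table[model].items()}

    def standard_errors(self, model: str) -> dict[str, float]:
        return {term: se for term, (_, se) in self.coefficient_table[model].items()}

    @property
    def n_cohort(self) -> int:
        return sum(t.n_total for t in self.trial_table)

    @property
    def n_placebo(self) -> int:
        return sum(t.n_placebo for t in self.trial_table)

    @property
    def n_active(self) -> int:
        return sum(t.n_active for t in self.trial_table)


_CONSTANTS = PublishedConstants()


def published_constants() -> PublishedConstants:
    """The packaged published constants (immutable, referentially transparent)."""
    return _CONSTANTS


def population_centers() -> dict[str, float]:
    """Cohort-size-weighted means of the continuous covariates across
    the published trials — the centering constants implied by pooled
    centering of the full cohort."""
    w = [t.n_total for t in TRIAL_TABLE]
    total = sum(w)

    def wmean(values):
        return sum(wi * v for wi, v in zip(w, values)) / total

    return {
        "year": wmean([t.year for t in TRIAL_TABLE]),
        "age": wmean([t.age[0] for t in TRIAL_TABLE]),
        "bmi": wmean([t.bmi[0] for t in TRIAL_TABLE]),
        "baseline_cdai": wmean([t.baseline_cdai[0] for t in TRIAL_TABLE]),
        "crp": wmean([t.crp[0] for t in TRIAL_TABLE]),
    }
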