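"""Counterfactual simulation and preference-pattern subgroups.

For every participant, the three drug-class models yield simulated
conditional-mean responses under each counterfactual treatment.  A
parametric bootstrap — coefficient vectors drawn from a multivariate
normal centered at the estimates with the fitted coefficient
covariance, random effects set to 0 — gives each prediction a median
and a standard error; an analytic closed form sqrt(x' V x) is available
for real-time use.  Pairwise two-sided tests at a nominal alpha of 0.05
turn the three predictions into a preference pattern: a weak ordering
over the classes (with ties for statistical indistinguishability), or
"inconsistent" for the cyclic outcome triples no ordering explains.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FittedMixedModel
from .schema import ANTI_IL1223, ANTI_INTEGRIN, ANTI_TNF, CLASS_TAGS, CohortTable

#: canonical class order for pair enumeration
CLASS_ORDER = (ANTI_TNF, ANTI_IL1223, ANTI_INTEGRIN)
#: the three unordered class pairs, canonical order
PAIRS = ((ANTI_TNF, ANTI_IL1223), (ANTI_TNF, ANTI_INTEGRIN),
         (ANTI_IL1223, ANTI_INTEGRIN))

NO_PREFERENCE = "no preference"
INCONSISTENT = "inconsistent"


class Comparison(str, Enum):
    FIRST_SUPERIOR = "first_superior"
    SECOND_SUPERIOR = "second_superior"
    INDISTINGUISHABLE = "indistinguishable"


@dataclass(frozen=True)
class PredictionSummary:
    """Per-patient conditional-mean effect for one drug class."""

    drug_class: str
    point: float
    se: float
    n_draws: int = 0
    method: str = "analytic"

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("negative standard error")
        if self.method == "parametric_bootstrap" and self.n_draws < 1:
            raise ValueError("bootstrap summary needs n_draws >= 1")


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    scale = np.abs(cov).max() or 1.0
    if not np.allclose(cov, cov.T, atol=1e-8 * scale):
        raise ValueError("covariance matrix is not symmetric")
    cov = (cov + cov.T) / 2.0
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance matrix is not positive semi-definite")
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def bootstrap_prediction(model: FittedMixedModel, record, n_draws: int,
                         seed) -> PredictionSummary:
    """Parametric-bootstrap prediction summary for one participant.

    Draws ``n_draws`` coefficient vectors from MVN(beta, V), evaluates
    x'beta for each, and summarises as the median (point) and SD (se)
    of the draws.  Deterministic given ``seed`` (an int or a numpy
    SeedSequence/Generator).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = model.design_row(record)
    b = np.array([model.beta[t] for t in model.terms])
    L = _psd_cholesky(model.cov)
    draws = b + rng.standard_normal((n_draws, len(b))) @ L.T
    preds = draws @ x
    return PredictionSummary(
        drug_class=model.name, point=float(np.median(preds)),
        se=float(np.std(preds, ddof=1)), n_draws=n_draws,
        method="parametric_bootstrap")


def analytic_se(model: FittedMixedModel, record) -> float:
    """Closed-form SE of the conditional-mean prediction:
    sqrt(x' V x) for the centered design vector x."""
    x = model.design_row(record)
    return float(np.sqrt(x @ np.asarray(model.cov) @ x))


def analytic_prediction(model: FittedMixedModel, record) -> PredictionSummary:
    return PredictionSummary(drug_class=model.name,
                             point=model.predict(record),
                             se=analytic_se(model, record),
                             method="analytic")


def pairwise_test(a: PredictionSummary, b: PredictionSummary,
                  alpha: float = 0.05) -> tuple[Comparison, float]:
    """Two-sided normal test of a difference between two prediction
    summaries.  Returns (outcome, p-value); the outcome is superiority
    of the larger point estimate when p < alpha."""
    denom = float(np.hypot(a.se, b.se))
    diff = a.point - b.point
    if denom == 0.0:
        if diff == 0.0:
            return Comparison.INDISTINGUISHABLE, 1.0
        p = 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(diff) / denom))
    if p < alpha:
        return (Comparison.FIRST_SUPERIOR if diff > 0
                else Comparison.SECOND_SUPERIOR), p
    return Comparison.INDISTINGUISHABLE, p


# ---------------------------------------------------------------------------
# the preference-pattern lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferencePattern:
    """Outcome of the three pairwise comparisons for one patient."""

    pairwise: tuple  # Comparison per pair in PAIRS order
    label: str
    top_tier: frozenset

    @property
    def consistent(self) -> bool:
        return self.label != INCONSISTENT


def _tier_label(tiers: tuple[tuple[str, ...], ...]) -> str:
    """Human-readable label for a weak ordering given as tiers,
    best first.  Tie formatting follows the published convention:
    (IL = TNF), (TNF = INT), (IL = INT)."""
    tie_order = {frozenset({ANTI_TNF, ANTI_IL1223}): (ANTI_IL1223, ANTI_TNF),
                 frozenset({ANTI_TNF, ANTI_INTEGRIN}): (ANTI_TNF, ANTI_INTEGRIN),
                 frozenset({ANTI_IL1223, ANTI_INTEGRIN}): (ANTI_IL1223, ANTI_INTEGRIN)}
    if len(tiers) == 1:
        return NO_PREFERENCE
    parts = []
    for tier in tiers:
        if len(tier) == 1:
            parts.append(CLASS_TAGS[tier[0]])
        else:
            ordered = tie_order[frozenset(tier)]
            parts.append("(" + " = ".join(CLASS_TAGS[c] for c in ordered) + ")")
    return " > ".join(parts)


def _all_weak_orderings():
    """All 13 weak orderings of the three classes, as tier tuples."""
    a, b, c = CLASS_ORDER
    orders = [((a, b, c),)]  # single tier: all tied
    for top, rest in [((x,), tuple(y for y in CLASS_ORDER if y != x))
                      for x in CLASS_ORDER]:
        orders.append((top, rest))           # X > (Y = Z)
        orders.append((rest, top))           # (Y = Z) > X
    for perm in itertools.permutations(CLASS_ORDER):
        orders.append(((perm[0],), (perm[1],), (perm[2],)))
    return orders


def _pairwise_of_ordering(tiers) -> tuple:
    rank = {}
    for depth, tier in enumerate(tiers):
        for cls in tier:
            rank[cls] = depth
    out = []
    for x, y in PAIRS:
        if rank[x] < rank[y]:
            out.append(Comparison.FIRST_SUPERIOR)
        elif rank[x] > rank[y]:
            out.append(Comparison.SECOND_SUPERIOR)
        else:
            out.append(Comparison.INDISTINGUISHABLE)
    return tuple(out)


def _build_lattice() -> dict[tuple, PreferencePattern]:
    table: dict[tuple, PreferencePattern] = {}
    for tiers in _all_weak_orderings():
        key = _pairwise_of_ordering(tiers)
        table[key] = PreferencePattern(
            pairwise=key, label=_tier_label(tiers),
            top_tier=frozenset(tiers[0]))
    for key in itertools.product(list(Comparison), repeat=3):
        if key not in table:
            table[key] = PreferencePattern(pairwise=key, label=INCONSISTENT,
                                           top_tier=frozenset())
    return table


_LATTICE = _build_lattice()

#: the published labels plus every other consistent weak ordering
ALL_CONSISTENT_LABELS = sorted({p.label for p in _LATTICE.values()
                                if p.consistent})


def assign_subgroup(outcomes) -> PreferencePattern:
    """Map the three pairwise outcomes (PAIRS order: TNF/IL, TNF/INT,
    IL/INT) to a preference pattern.  Total over all 27 triples; the
    14 cyclic triples map to "inconsistent"."""
    key = tuple(Comparison(o) for o in outcomes)
    if len(key) != 3:
        raise ValueError("expected exactly three pairwise outcomes")
    return _LATTICE[key]


#: top tiers whose tie is reported as "Other" rather than credited to
#: the tied classes, following the published subgroup-table convention
#: (a tie with the anti-integrin class at the top is not counted as
#: either class being "tied for best")
_OTHER_TIES = (frozenset({ANTI_TNF, ANTI_INTEGRIN}),
               frozenset({ANTI_IL1223, ANTI_INTEGRIN}))


def subgroup_census(patterns) -> dict:
    """Counts per label plus best-or-tied / strictly-best aggregates.

    ``patterns`` is an iterable of PreferencePattern (or of labels), or
    a mapping label -> count.  "Strictly best" counts patterns whose
    top tier is exactly one class.  "Best or tied" follows the
    published grouping: top tiers that pair a class with the
    anti-integrin class are filed under "other" and credited to
    neither; ``top_tier_contains`` gives the unfiltered lattice count
    (every pattern whose top tier contains the class).
    """
    if isinstance(patterns, dict):
        counts = {str(k): int(v) for k, v in patterns.items()}
    else:
        counts = {}
        for p in patterns:
            label = p.label if isinstance(p, PreferencePattern) else str(p)
            counts[label] = counts.get(label, 0) + 1
    label_info = {p.label: p.top_tier for p in _LATTICE.values()}
    best_or_tied = {c: 0 for c in CLASS_ORDER}
    top_tier_contains = {c: 0 for c in CLASS_ORDER}
    strictly_best = {c: 0 for c in CLASS_ORDER}
    n_other = 0
    for label, n in counts.items():
        if label in (NO_PREFERENCE, INCONSISTENT):
            continue
        top = label_info.get(label)
        if top is None:
            raise ValueError(f"unknown subgroup label {label!r}")
        for c in top:
            top_tier_contains[c] += n
        if top in _OTHER_TIES:
            n_other += n
        else:
            for c in top:
                best_or_tied[c] += n
        if len(top) == 1:
            strictly_best[next(iter(top))] += n
    return {"counts": counts, "total": sum(counts.values()),
            "best_or_tied": best_or_tied,
            "top_tier_contains": top_tier_contains,
            "strictly_best": strictly_best, "n_other": n_other}


# ---------------------------------------------------------------------------
# whole-cohort assignment
# ---------------------------------------------------------------------------

def _predict_all(model: FittedMixedModel, df: pd.DataFrame, n_draws: int,
                 seeds, method: str):
    """Vectorised per-patient predictions; per-patient substreams keep
    the result independent of evaluation order."""
    X = model.design(df)
    b = np.array([model.beta[t] for t in model.terms])
    V = np.asarray(model.cov)
    if method == "analytic":
        points = X @ b
        ses = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
        return points, ses
    L = _psd_cholesky(V)
    points = np.empty(len(df))
    ses = np.empty(len(df))
    for i in range(len(df)):
        rng = np.random.default_rng(seeds[i])
        draws = b + rng.standard_normal((n_draws, len(b))) @ L.T
        preds = draws @ X[i]
        points[i] = np.median(preds)
        ses[i] = np.std(preds, ddof=1)
    return points, ses


def assign_all(cohort: CohortTable, models: dict[str, FittedMixedModel],
               n_draws: int = 10_000, alpha: float = 0.05,
               seed: int = 0, method: str = "parametric_bootstrap"
               ) -> pd.DataFrame:
    """Assign every participant (both arms) a preference pattern.

    Returns a table with per-class points and SEs, the three pairwise
    outcomes, the label, and the top tier.  Reproducible given
    ``seed``: patient i's draws for class c come from the substream
    SeedSequence([seed, i, class index]).
    """
    df = cohort.records.reset_index(drop=True)
    if set(models) < set(CLASS_ORDER):
        raise ValueError("need one fitted model per drug class")
    cols = {"participant_id": df["participant_id"]}
    summaries = {}
    for ci, cls in enumerate(CLASS_ORDER):
        if method == "parametric_bootstrap":
            seeds = [np.random.SeedSequence([seed, i, ci])
                     for i in range(len(df))]
        else:
            seeds = None
        pts, ses = _predict_all(models[cls], df, n_draws, seeds, method)
        tag = CLASS_TAGS[cls].lower()
        cols[f"point_{tag}"] = pts
        cols[f"se_{tag}"] = ses
        summaries[cls] = (pts, ses)
    out = pd.DataFrame(cols)
    labels, tops = [], []
    pair_cols = {f"cmp_{CLASS_TAGS[x].lower()}_{CLASS_TAGS[y].lower()}": []
                 for x, y in PAIRS}
    for i in range(len(df)):
        outcomes = []
        for (x, y), col in zip(PAIRS, pair_cols):
            ax = PredictionSummary(x, summaries[x][0][i], summaries[x][1][i],
                                   n_draws, method)
            by = PredictionSummary(y, summaries[y][0][i], summaries[y][1][i],
                                   n_draws, method)
            cmp_, _ = pairwise_test(ax, by, alpha)
            outcomes.append(cmp_)
            pair_cols[col].append(cmp_.value)
        pat = assign_subgroup(outcomes)
        labels.append(pat.label)
        tops.append("+".join(sorted(CLASS_TAGS[c] for c in pat.top_tier)))
    for col, vals in pair_cols.items():
        out[col] = vals
    out["label"] = labels
    out["top_tier"] = tops
    return out
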