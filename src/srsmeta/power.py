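"""Prospective-trial power simulation.

Bootstraps pairs of study arms from a (filtered) reference population,
converts each sampled patient's model-predicted week-6 CDAI reduction
into a probability of clinical response (a reduction of >= 100 points)
under conditional normality, and estimates the power of a chi-squared
comparison of responder counts between the two arms.

Two ways of forming the responder counts are available:

``expected``
    Round the arm-average response probability times the arm size — a
    deterministic expected count.  This is the default.  Because the
    spread of per-patient probabilities is narrower than binomial
    noise, the test is conservative under the null in this mode.
``observed``
    Draw each patient's responder status Bernoulli(p) and count.  The
    mixture makes the count variance exactly binomial, so the nominal
    level holds under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
import operator
import re

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FittedMixedModel
from .schema import PLACEBO, CohortTable

RESPONSE_THRESHOLD = 100.0


@dataclass(frozen=True)
class PowerEstimate:
    filter_description: str
    arm_size: int
    n_sims: int
    alpha: float
    power: float

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the power estimate."""
        return float(np.sqrt(self.power * (1.0 - self.power) / self.n_sims))


def response_probability(mu, sigma, threshold: float = RESPONSE_THRESHOLD):
    """P(outcome >= threshold) for a Normal(mu, sigma) outcome.

    With sigma = 0 this degenerates to the indicator of mu >= threshold.
    Vectorised over mu.
    """
    mu = np.asarray(mu, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        out = (mu >= threshold).astype(float)
    else:
        out = stats.norm.sf((threshold - mu) / sigma)
    return float(out) if out.ndim == 0 else out


_OPS = {">=": operator.ge, "<=": operator.le, "!=": operator.ne,
        "==": operator.eq, ">": operator.gt, "<": operator.lt,
        "=": operator.eq}
_FILTER_RE = re.compile(r"^\s*(\w+)\s*(>=|<=|!=|==|=|>|<)\s*(\S+)\s*$")


def parse_filter(spec: str):
    """Build a row predicate from a comma/'and'-separated spec such as
    ``"sex == female, age > 50"``.  Returns a callable on a DataFrame
    producing a boolean mask."""
    clauses = []
    for part in re.split(r",|\band\b", spec):
        if not part.strip():
            continue
        m = _FILTER_RE.match(part)
        if m is None:
            raise ValueError(f"cannot parse filter clause {part!r}")
        fld, op, raw = m.groups()
        try:
            val: object = float(raw)
        except ValueError:
            val = {"true": True, "false": False}.get(raw.lower(), raw)
        clauses.append((fld, _OPS[op], val))

    def predicate(df: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(df), dtype=bool)
        for fld, op, val in clauses:
            if fld not in df.columns:
                raise ValueError(f"unknown filter field {fld!r}")
            mask &= op(df[fld], val).to_numpy(dtype=bool)
        return mask

    predicate.description = spec
    return predicate


def simulate_trial_power(population: CohortTable, filter_predicate,
                         classes: tuple[str, str], arm_size: int,
                         models: dict[str, FittedMixedModel],
                         placebo_model: FittedMixedModel, *,
                         n_sims: int = 1000, alpha: float = 0.05,
                         seed: int = 0, sigma_mode: str = "combined",
                         count_mode: str = "expected") -> PowerEstimate:
    """Estimate power of a two-arm head-to-head trial.

    Per simulation, two arms of ``arm_size`` are sampled with
    replacement from the filtered population; each patient's expected
    reduction is placebo prediction plus the arm's drug-class
    prediction, converted to a response probability under conditional
    normality with the fitted residual SD (``sigma_mode``: "combined"
    uses sqrt(placebo + class residual variance), "class_only" the
    class variance alone).  Responder counts per ``count_mode`` (module
    docstring) are compared by a 2x2 chi-squared test without
    continuity correction; power is the rejection fraction.
    """
    if callable(filter_predicate):
        mask = filter_predicate(population.records)
        desc = getattr(filter_predicate, "description", "custom predicate")
    else:
        filter_predicate = parse_filter(filter_predicate)
        mask = filter_predicate(population.records)
        desc = filter_predicate.description
    pool = population.records[mask].reset_index(drop=True)
    if len(pool) == 0:
        raise ValueError(f"filter {desc!r} matched no participants")
    if sigma_mode not in ("combined", "class_only"):
        raise ValueError("sigma_mode must be 'combined' or 'class_only'")
    if count_mode not in ("expected", "observed"):
        raise ValueError("count_mode must be 'expected' or 'observed'")

    # per-patient expected reductions and response probabilities per class
    probs = {}
    base = placebo_model.predict(pool)
    for cls in classes:
        mdl = models[cls]
        mu = base + mdl.predict(pool)
        sigma = float(np.sqrt(mdl.sigma_sq + (placebo_model.sigma_sq
                                              if sigma_mode == "combined"
                                              else 0.0)))
        probs[cls] = response_probability(mu, sigma)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x50E2]))
    rejections = 0
    n_pool = len(pool)
    for _ in range(n_sims):
        counts = []
        for cls in classes:
            idx = rng.integers(0, n_pool, arm_size)
            p = probs[cls][idx]
            if count_mode == "expected":
                responders = int(round(p.mean() * arm_size))
            else:
                responders = int((rng.random(arm_size) < p).sum())
            counts.append(responders)
        table = np.array([[counts[0], arm_size - counts[0]],
                          [counts[1], arm_size - counts[1]]])
        if table[:, 0].sum() in (0, 2 * arm_size):
            continue  # degenerate table, never rejects
        _, p_val, _, _ = stats.chi2_contingency(table, correction=False)
        if p_val < alpha:
            rejections += 1
    return PowerEstimate(filter_description=desc, arm_size=arm_size,
                         n_sims=n_sims, alpha=alpha,
                         power=rejections / n_sims)
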