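"""Reusable simulation experiments.

The parameter-recovery experiment regenerates synthetic cohorts with
the published coefficient sets as ground truth, runs the full
sequential fit (placebo model, residualization, drug-class models) and
collects the recovered coefficients.  Per replicate, every trial's arm
sizes are scaled proportionally so each model's fitting sample reaches
a target size (default 50,000), keeping the published per-trial
covariate mixture and trial structure intact.

Outcomes are generated noise-complete (no missingness injection): the
recovery experiment characterises the estimator under the modeled
data-generating process; the robustness of the harmonization rules is
exercised separately.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import fit_all
from .generator import GeneratorConfig, default_config, generate_covariates, simulate_outcomes
from .harmonize import harmonize
from .schema import DRUG_CLASSES, PLACEBO


def scaled_config(base: GeneratorConfig, n_target: int = 50_000
                  ) -> GeneratorConfig:
    """Scale every trial's arms so each model's fitting sample
    (placebo pool and each drug class pool) totals ~``n_target``."""
    n_placebo = sum(t.n_placebo for t in base.trials)
    n_class = {c: sum(t.n_active for t in base.trials if t.drug_class == c)
               for c in DRUG_CLASSES}
    trials = tuple(
        replace(t,
                n_active=int(round(t.n_active * n_target / n_class[t.drug_class])),
                n_placebo=int(round(t.n_placebo * n_target / n_placebo)))
        for t in base.trials)
    return replace(base, trials=trials)


def recovery_simulation(n_seeds: int = 10, n_target: int = 50_000,
                        base_seed: int = 1) -> pd.DataFrame:
    """Fit the sequential models on ``n_seeds`` independent synthetic
    cohorts and return a tidy table of recovered coefficients.

    Columns: seed, model, term, estimate, truth.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = scaled_config(default_config(seed), n_target)
        cohort = generate_covariates(cfg, seed)
        cohort = simulate_outcomes(cohort, cfg, seed)
        cohort, _ = harmonize(cohort)
        placebo, drugs, _ = fit_all(cohort)
        for model in [placebo] + list(drugs.values()):
            truth = (cfg.beta_placebo if model.name == PLACEBO
                     else cfg.beta_drug[model.name])
            for term in model.terms:
                rows.append({"seed": seed, "model": model.name, "term": term,
                             "estimate": model.beta[term],
                             "truth": truth[term]})
    return pd.DataFrame(rows)


def recovery_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean recovered coefficient, empirical SE of the mean, and truth
    per (model, term)."""
    g = results.groupby(["model", "term"], sort=False)
    out = g.agg(mean=("estimate", "mean"),
                sd=("estimate", "std"),
                truth=("truth", "first"),
                n_seeds=("estimate", "size")).reset_index()
    out["se_mean"] = out["sd"] / np.sqrt(out["n_seeds"])
    return out


def narrated_effects(summary: pd.DataFrame) -> dict[str, float]:
    """The headline effect sizes on the scales the narration uses.

    - placebo baseline-CDAI slope per 100 points
    - magnitude of the placebo prior-anti-TNF coefficient
    - anti-TNF and anti-integrin age effects per decade (sign flipped:
      points *less* per decade)
    - anti-IL-12/23 steroid coefficient
    """

    def pick(model, term):
        row = summary[(summary["model"] == model) & (summary["term"] == term)]
        return float(row["mean"].iloc[0]), float(row["se_mean"].iloc[0])

    cdai, cdai_se = pick("placebo", "baseline_cdai")
    tnfh, tnfh_se = pick("placebo", "tnf_history")
    age_tnf, age_tnf_se = pick("anti_tnf", "age")
    age_int, age_int_se = pick("anti_integrin", "age")
    ster, ster_se = pick("anti_il1223", "steroid")
    return {
        "placebo_cdai_per_100": 100.0 * cdai,
        "placebo_cdai_per_100_se": 100.0 * cdai_se,
        "placebo_tnf_history_magnitude": abs(tnfh),
        "placebo_tnf_history_magnitude_se": tnfh_se,
        "tnf_age_per_decade": -10.0 * age_tnf,
        "tnf_age_per_decade_se": 10.0 * age_tnf_se,
        "integrin_age_per_decade": -10.0 * age_int,
        "integrin_age_per_decade_se": 10.0 * age_int_se,
        "il_steroid": ster,
        "il_steroid_se": ster_se,
    }
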