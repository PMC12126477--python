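"""Sequential regression: placebo and drug-class mixed models.

The two-stage procedure normalizes pooled trial data against a common
placebo background:

1. Fit a linear mixed model of the week-6 CDAI reduction on the placebo
   arms — centered continuous covariates and study year as fixed
   effects, trial of origin as a random intercept.
2. Predict each actively treated participant's placebo-attributable
   response (random effects set to 0), subtract it from the observed
   response, and fit one mixed model per drug class on the residual,
   drug-attributable reduction (same covariates, no year term).

Models are estimated by REML; likelihood-ratio tests against
intercept-only models refit both with full ML.  Wald tests use the
large-sample normal reference.

Centering constants are the pooled means of each model's fitting sample
and are persisted with the model: predictions always reuse the stored
centers, never recompute them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
import statsmodels.api as sm

from .constants import DRUG_TERMS, PLACEBO_TERMS
from .schema import DRUG_CLASSES, PLACEBO, CohortTable

logger = logging.getLogger(__name__)

#: covariates whose design column is the raw value minus the stored center
CENTERED_TERMS = ("year", "baseline_cdai", "age", "bmi", "crp")


class SingleTrialError(ValueError):
    """Random intercept inestimable: the fitting sample has one trial."""


class RankDeficientError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass
class FittedMixedModel:
    """A fitted random-intercept linear mixed model of CDAI reduction.

    Attributes
    ----------
    name : str
        ``"placebo"`` or a drug class.
    terms : tuple of str
        Ordered fixed-effect terms, ``intercept`` first.
    beta : dict
        term -> coefficient (CDAI points per unit).
    cov : ndarray
        Covariance of the fixed-effect estimates, term order.
    tau_sq, sigma_sq : float
        Random-intercept and residual variances (CDAI points squared).
    centers : dict
        Covariate -> centering constant used to build the design.
    random_effects : dict
        trial_id -> predicted (BLUP) trial intercept, for diagnostics.
    method : str
        ``"reml"`` or ``"ols"`` (single-trial fall-back).
    """

    name: str
    terms: tuple
    beta: dict
    cov: np.ndarray
    tau_sq: float
    sigma_sq: float
    centers: dict
    log_likelihood: float
    n_obs: int
    random_effects: dict = field(default_factory=dict)
    method: str = "reml"

    # -- design ------------------------------------------------------------

    def design_row(self, record) -> np.ndarray:
        """Centered design vector for one record (mapping or Series)."""
        return _design_matrix(pd.DataFrame([dict(record)]), self.terms,
                              self.centers)[0]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        return _design_matrix(df, self.terms, self.centers)

    def predict(self, records) -> np.ndarray | float:
        """Conditional-mean prediction x'beta, random effects 0.

        Accepts a DataFrame (returns an array) or a single mapping /
        Series (returns a float).
        """
        single = not isinstance(records, pd.DataFrame)
        df = pd.DataFrame([dict(records)]) if single else records
        X = _design_matrix(df, self.terms, self.centers)
        b = np.array([self.beta[t] for t in self.terms])
        out = X @ b
        return float(out[0]) if single else out

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {"name": self.name, "terms": list(self.terms),
                "beta": self.beta, "cov": np.asarray(self.cov).tolist(),
                "tau_sq": self.tau_sq, "sigma_sq": self.sigma_sq,
                "centers": self.centers,
                "log_likelihood": self.log_likelihood, "n_obs": self.n_obs,
                "random_effects": self.random_effects, "method": self.method}

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMixedModel":
        d = dict(d)
        d["terms"] = tuple(d["terms"])
        d["cov"] = np.asarray(d["cov"], dtype=float)
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedMixedModel":
        with open(path) as fh:
            d = json.load(fh)
        try:
            return cls.from_dict(d)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"corrupted model file {path}: {exc}") from exc


def _design_matrix(df: pd.DataFrame, terms, centers) -> np.ndarray:
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(df)))
        elif term == "sex_male":
            if "sex_male" in df.columns:
                cols.append(df["sex_male"].to_numpy(dtype=float))
            else:
                cols.append((df["sex"].to_numpy() == "male").astype(float))
        elif term in CENTERED_TERMS:
            if term not in df.columns or df[term].isna().any():
                raise ValueError(f"missing covariate {term!r}")
            cols.append(df[term].to_numpy(dtype=float) - centers[term])
        else:  # uncentered boolean
            if term not in df.columns or df[term].isna().any():
                raise ValueError(f"missing covariate {term!r}")
            cols.append(df[term].to_numpy(dtype=float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name offending columns: tiny diagonal entries of the QR factor
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = r.max() * max(X.shape) * np.finfo(float).eps
        bad = [t for t, d in zip(terms, r) if d < tol]
        raise RankDeficientError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad or list(terms)}")


def _fit_lmm(df: pd.DataFrame, terms, centers, name: str,
             reml: bool = True) -> FittedMixedModel:
    y = df["reduction_week6"].to_numpy(dtype=float)
    X = _design_matrix(df, terms, centers)
    _check_rank(X, terms)
    groups = df["trial_id"].to_numpy()
    n_trials = len(np.unique(groups))
    if n_trials < 2:
        raise SingleTrialError(
            f"{name}: only {n_trials} trial in the fitting sample; "
            "the trial random intercept is inestimable")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # powell is the most reliable profile-likelihood optimizer here;
        # gradient-based fallbacks can park on a degenerate boundary
        for opt in ("powell", "nm", "lbfgs"):
            cand = MixedLM(y, X, groups=groups).fit(reml=reml, method=opt,
                                                    maxiter=2000)
            if cand.converged:
                res = cand
                break
        if res is None:
            logger.warning("%s: mixed-model optimizer did not converge; "
                           "using the last attempt", name)
            res = cand
    beta = {t: float(b) for t, b in zip(terms, res.fe_params)}
    tau_sq = float(np.asarray(res.cov_re)[0, 0])
    sigma_sq = float(res.scale)
    # model-based covariance of the fixed effects, (X' Sigma^-1 X)^-1,
    # via Woodbury per trial; stays well-defined when tau_sq hits 0
    # (the Hessian-based covariance does not)
    A = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        Xg = X[groups == g]
        s1 = Xg.sum(axis=0)
        ng = len(Xg)
        shrink = tau_sq / (sigma_sq * (sigma_sq + ng * tau_sq))
        A += Xg.T @ Xg / sigma_sq - shrink * np.outer(s1, s1)
    cov = np.linalg.inv(A)
    cov = (cov + cov.T) / 2.0
    try:
        re = {str(g): float(v.iloc[0]) for g, v in res.random_effects.items()}
    except (ValueError, np.linalg.LinAlgError):
        # RE variance estimated at zero: BLUPs degenerate to zero
        re = {str(g): 0.0 for g in np.unique(groups)}
    return FittedMixedModel(
        name=name, terms=tuple(terms), beta=beta, cov=cov,
        tau_sq=tau_sq, sigma_sq=sigma_sq,
        centers=dict(centers),
        log_likelihood=float(res.llf), n_obs=len(df),
        random_effects=re, method="reml" if reml else "ml")


def _pooled_centers(df: pd.DataFrame, terms) -> dict:
    return {t: float(df[t].mean()) for t in CENTERED_TERMS if t in terms}


def published_model(name: str) -> FittedMixedModel:
    """A :class:`FittedMixedModel` built from the packaged published
    coefficient table for ``name`` (``"placebo"`` or a drug class).

    The coefficient covariance is the diagonal of the published squared
    standard errors (the off-diagonal covariances were not published),
    and the centering constants are the size-weighted covariate means
    of the published cohort.  Suitable for worked examples and for
    driving the decision tool without refitting.
    """
    from . import constants as _c
    coefs = _c.published_constants().coefficients(name)
    ses = _c.published_constants().standard_errors(name)
    terms = tuple(coefs)
    return FittedMixedModel(
        name=name, terms=terms, beta=dict(coefs),
        cov=np.diag([ses[t] ** 2 for t in terms]),
        tau_sq=0.0, sigma_sq=90.0 ** 2,
        centers=_c.population_centers(),
        log_likelihood=float("nan"), n_obs=0, method="published")


def published_models() -> dict[str, FittedMixedModel]:
    """Placebo plus the three drug-class published models."""
    return {name: published_model(name)
            for name in (PLACEBO,) + tuple(DRUG_CLASSES)}


def fit_placebo_model(cohort: CohortTable) -> FittedMixedModel:
    """REML fit of the placebo-response mixed model.

    Uses placebo-arm records with an observed outcome; covariates must
    be harmonized (complete) first.
    """
    df = cohort.records
    df = df[(df["arm"] == PLACEBO) & df["reduction_week6"].notna()]
    df = df.reset_index(drop=True)
    if len(df) <= len(PLACEBO_TERMS):
        raise ValueError(f"too few placebo records ({len(df)}) to fit "
                         f"{len(PLACEBO_TERMS)} fixed effects")
    centers = _pooled_centers(df, PLACEBO_TERMS)
    return _fit_lmm(df, PLACEBO_TERMS, centers, PLACEBO)


def predict_placebo(model: FittedMixedModel, record) -> float:
    """Placebo-attributable CDAI reduction for one participant,
    random effects set to 0."""
    return model.predict(record)


@dataclass
class ResidualizedCohort:
    """Active-arm records with the placebo-attributable prediction
    (``placebo_hat``) and the drug-attributable residual
    (``drug_attributable`` = observed − placebo_hat) attached."""

    records: pd.DataFrame
    n_excluded_no_outcome: int = 0


def residualize(cohort: CohortTable, placebo_model: FittedMixedModel,
                use_random_effects: bool = False) -> ResidualizedCohort:
    """Subtract the predicted placebo response from each actively
    treated participant's observed response.

    ``use_random_effects=True`` adds the fitted trial intercept (when
    the trial was in the placebo fitting sample) to the placebo
    prediction; the default follows the marginal, random-effects-zero
    convention.
    """
    df = cohort.records
    active = df[df["arm"] != PLACEBO]
    n_no_outcome = int(active["reduction_week6"].isna().sum())
    if n_no_outcome:
        logger.warning("residualize: excluding %d active records without "
                       "an observed outcome", n_no_outcome)
    active = active[active["reduction_week6"].notna()].reset_index(drop=True)
    yhat = placebo_model.predict(active)
    if use_random_effects:
        re = active["trial_id"].map(placebo_model.random_effects)
        yhat = yhat + re.fillna(0.0).to_numpy(dtype=float)
    out = active.copy()
    out["placebo_hat"] = yhat
    out["drug_attributable"] = out["reduction_week6"] - yhat
    return ResidualizedCohort(out, n_excluded_no_outcome=n_no_outcome)


def fit_drug_models(residualized: ResidualizedCohort
                    ) -> dict[str, FittedMixedModel]:
    """One random-intercept LMM of the drug-attributable residual per
    drug class (nine centered covariates, no year term).

    A class whose records come from a single trial falls back to a
    fixed-effects-only (OLS) fit, logged loudly and tagged
    ``method="ols"``.
    """
    out: dict[str, FittedMixedModel] = {}
    df = residualized.records
    for cls in DRUG_CLASSES:
        sub = df[df["arm"] == cls].reset_index(drop=True)
        if len(sub) == 0:
            continue
        sub = sub.copy()
        sub["reduction_week6"] = sub["drug_attributable"]
        centers = _pooled_centers(sub, DRUG_TERMS)
        try:
            out[cls] = _fit_lmm(sub, DRUG_TERMS, centers, cls)
        except SingleTrialError:
            logger.warning("drug class %s has a single trial; falling back "
                           "to a fixed-effects-only fit (no trial random "
                           "intercept)", cls)
            out[cls] = _fit_ols(sub, DRUG_TERMS, centers, cls)
    return out


def _fit_ols(df, terms, centers, name) -> FittedMixedModel:
    y = df["reduction_week6"].to_numpy(dtype=float)
    X = _design_matrix(df, terms, centers)
    _check_rank(X, terms)
    res = sm.OLS(y, X).fit()
    return FittedMixedModel(
        name=name, terms=tuple(terms),
        beta={t: float(b) for t, b in zip(terms, res.params)},
        cov=np.asarray(res.cov_params()),
        tau_sq=0.0, sigma_sq=float(res.scale), centers=dict(centers),
        log_likelihood=float(res.llf), n_obs=len(df),
        random_effects={}, method="ols")


def lrt_vs_intercept(model: FittedMixedModel, data: CohortTable | pd.DataFrame
                     ) -> dict:
    """Likelihood-ratio test of the fitted model against an
    intercept-only model, both refit with full ML on the same rows.

    ``data`` must be the model's fitting sample: for the placebo model
    the harmonized placebo arm; for a drug model the residualized class
    subset (with ``drug_attributable`` as outcome).
    """
    df = data.records if hasattr(data, "records") else data
    df = df.copy()
    if model.name != PLACEBO and "drug_attributable" in df.columns:
        df["reduction_week6"] = df["drug_attributable"]
    df = df[df["reduction_week6"].notna()].reset_index(drop=True)
    if len(df) != model.n_obs:
        raise ValueError(f"data has {len(df)} usable rows but the model "
                         f"was fit on {model.n_obs}")
    full = _fit_lmm(df, model.terms, model.centers, model.name, reml=False)
    null = _fit_lmm(df, ("intercept",), {}, model.name + "_null", reml=False)
    stat = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    df_slopes = len(model.terms) - 1
    p = float(stats.chi2.sf(stat, df_slopes)) if df_slopes else 1.0
    if stat == 0.0:
        p = 1.0
    return {"statistic": stat, "df": df_slopes, "p_value": p}


def wald_tests(model: FittedMixedModel) -> pd.DataFrame:
    """Per-term estimate, SE (sqrt of the covariance diagonal) and
    two-sided normal p-value."""
    se = np.sqrt(np.diag(model.cov))
    est = np.array([model.beta[t] for t in model.terms])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"estimate": est, "se": se, "p": p},
                        index=list(model.terms))


def fit_all(cohort: CohortTable, use_random_effects: bool = False
            ) -> tuple[FittedMixedModel, dict[str, FittedMixedModel],
                       ResidualizedCohort]:
    """Full sequential fit: placebo model, residualization, three drug
    models.  Returns (placebo model, drug models, residualized cohort)."""
    placebo = fit_placebo_model(cohort)
    resid = residualize(cohort, placebo, use_random_effects)
    drugs = fit_drug_models(resid)
    return placebo, drugs, resid
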