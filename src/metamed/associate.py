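"""Metabolome-wide association with BMI (linear) and T2D (logistic).

Each metabolite enters one regression at a time as the independent
variable of interest. The covariate tiers form a staircase: the basic
model adjusts for age and sex; lifestyle adds smoking status and physical
activity; the next tiers add systolic blood pressure, then HDL-C and
triglycerides, and the full model adds fasting glucose. T2D models always
additionally adjust for BMI; alcohol is never a covariate. Family-wise
error is controlled by Bonferroni over the retained metabolite panel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError, ModelError
from .preprocess import MetaboliteMatrix

__all__ = [
    "ModelSpec",
    "TIERS",
    "build_design",
    "fit_linear_assoc",
    "fit_logistic_assoc",
    "bonferroni_adjust",
    "model_staircase",
]

TIERS = ("basic", "lifestyle", "bp", "lipids", "full")

_TIER_COVARIATES: dict[str, list[str]] = {
    "basic": ["age", "sex"],
    "lifestyle": ["age", "sex", "smoking", "physical_activity"],
    "bp": ["age", "sex", "smoking", "physical_activity", "systolic_bp"],
    "lipids": [
        "age",
        "sex",
        "smoking",
        "physical_activity",
        "systolic_bp",
        "hdl_c",
        "triglycerides",
    ],
    "full": [
        "age",
        "sex",
        "smoking",
        "physical_activity",
        "systolic_bp",
        "hdl_c",
        "triglycerides",
        "fasting_glucose",
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome + covariate tier; resolves the covariate list.

    T2D specs always include BMI as a covariate; alcohol is never included.
    """

    outcome: str  # "bmi" or "t2d"
    tier: str = "full"

    def __post_init__(self) -> None:
        if self.outcome not in ("bmi", "t2d"):
            raise InputError(f"unknown outcome '{self.outcome}'")
        if self.tier not in TIERS:
            raise InputError(f"unknown covariate tier '{self.tier}'")

    @property
    def covariates(self) -> list[str]:
        covs = list(_TIER_COVARIATES[self.tier])
        if self.outcome == "t2d":
            covs.append("bmi")
        return covs


def build_design(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design columns for the named covariates.

    Categorical codings: sex → man dummy (reference woman); smoking → two
    dummies smoker and ex-smoker (reference never); physical activity →
    inactive dummy (reference active).
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex_man"] = (cohort["sex"] == "man").astype(float).to_numpy()
        elif cov == "smoking":
            cols["smoking_smoker"] = (cohort["smoking"] == "smoker").astype(float).to_numpy()
            cols["smoking_ex"] = (cohort["smoking"] == "ex-smoker").astype(float).to_numpy()
        elif cov == "physical_activity":
            cols["inactive"] = (
                (cohort["physical_activity"] == "inactive").astype(float).to_numpy()
            )
        else:
            cols[cov] = cohort[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=cohort.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name one culprit: a column whose removal restores full column rank
        for col in X.columns:
            rest = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(rest) == rest.shape[1]:
                raise ModelError(f"design matrix is rank deficient; collinear column: {col}")
        raise ModelError("design matrix is rank deficient")


def _align(metabolites: MetaboliteMatrix | pd.DataFrame, cohort: pd.DataFrame):
    data = metabolites.data if isinstance(metabolites, MetaboliteMatrix) else metabolites
    cohort = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    shared = data.index.intersection(cohort.index)
    if len(shared) == 0:
        raise InputError("no shared participants between metabolite matrix and cohort")
    return data.loc[shared], cohort.loc[shared]


def fit_linear_assoc(
    metabolites: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """OLS of BMI on each metabolite + the tier's covariates.

    Returns one row per metabolite: ``beta`` (kg/m² per SD of
    log-metabolite), SE, Wald 95% CI, two-sided p.
    """
    if spec.outcome != "bmi":
        raise InputError("fit_linear_assoc requires a BMI outcome spec")
    data, cohort = _align(metabolites, cohort)
    design = build_design(cohort, spec.covariates)
    keep = ~(design.isna().any(axis=1) | cohort["bmi"].isna())
    design, data = design[keep.to_numpy()], data[keep.to_numpy()]
    y = cohort.loc[keep, "bmi"].astype(float).to_numpy()

    rows = []
    for m in data.columns:
        X = pd.concat([data[[m]], design], axis=1)
        X = sm.add_constant(X, prepend=True)
        _check_rank(X)
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int().loc[m]
        rows.append(
            {
                "metabolite": m,
                "beta": fit.params[m],
                "se": fit.bse[m],
                "ci_low": ci[0],
                "ci_high": ci[1],
                "pvalue": fit.pvalues[m],
            }
        )
    return pd.DataFrame(rows)


def fit_logistic_assoc(
    metabolites: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit of T2D on each metabolite + covariates.

    Reports the coefficient on both the log-odds scale (``log_or``) and the
    exponentiated scale (``odds_ratio`` with Wald CI); complete separation
    or non-convergence yields a flagged row (``converged`` False), not a
    crash.
    """
    if spec.outcome != "t2d":
        raise InputError("fit_logistic_assoc requires a T2D outcome spec")
    data, cohort = _align(metabolites, cohort)
    design = build_design(cohort, spec.covariates)
    keep = ~(design.isna().any(axis=1) | cohort["t2d"].isna())
    design, data = design[keep.to_numpy()], data[keep.to_numpy()]
    y = cohort.loc[keep, "t2d"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("T2D outcome has a single class; logistic fit impossible")

    rows = []
    for m in data.columns:
        X = pd.concat([data[[m]], design], axis=1)
        X = sm.add_constant(X, prepend=True)
        _check_rank(X)
        converged = True
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
            beta, se, p = fit.params[m], fit.bse[m], fit.pvalues[m]
            ci = fit.conf_int().loc[m]
            lo, hi = ci[0], ci[1]
        except Exception:  # perfect separation and kin
            converged = False
            beta = se = p = lo = hi = np.nan
        rows.append(
            {
                "metabolite": m,
                "log_or": beta,
                "se": se,
                "odds_ratio": np.exp(beta),
                "or_ci_low": np.exp(lo),
                "or_ci_high": np.exp(hi),
                "pvalue": p,
                "converged": converged,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_adjust(
    results: pd.DataFrame, m_tests: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach Bonferroni q-values and significance flags.

    ``q = min(1, p·m)``; a result is significant when ``p < alpha/m``.
    ``m_tests`` defaults to the number of rows (the retained panel).
    """
    m = int(m_tests) if m_tests is not None else len(results)
    if m < 1:
        raise InputError("m_tests must be >= 1")
    p = results["pvalue"].to_numpy(dtype=float)
    finite = p[np.isfinite(p)]
    if len(finite) and ((finite < 0).any() or (finite > 1).any()):
        raise InputError("p-values outside [0, 1]")
    out = results.copy()
    out["qvalue"] = np.minimum(1.0, p * m)
    out["significant"] = p < alpha / m
    return out


def model_staircase(
    metabolites: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    m_tests: int | None = None,
    tiers: tuple[str, ...] = TIERS,
) -> pd.DataFrame:
    """Bonferroni-significant metabolite counts per covariate tier and outcome."""
    counts = []
    for tier in tiers:
        row = {"tier": tier}
        lin = fit_linear_assoc(metabolites, cohort, ModelSpec("bmi", tier))
        row["bmi"] = int(bonferroni_adjust(lin, m_tests, alpha)["significant"].sum())
        logi = fit_logistic_assoc(metabolites, cohort, ModelSpec("t2d", tier))
        row["t2d"] = int(bonferroni_adjust(logi, m_tests, alpha)["significant"].sum())
        counts.append(row)
    return pd.DataFrame(counts).set_index("tier")
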