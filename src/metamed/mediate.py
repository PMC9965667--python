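"""Sobel mediation screening of metabolites on the BMI → glycemia path.

The screen replicates a residualize-then-test construction: each
metabolite is first replaced by its residuals from an OLS regression on
seven confounders (age, sex, physical activity, smoking, systolic blood
pressure, HDL-C, triglycerides); the residual then enters the Sobel model
as the mediator with BMI as exposure and fasting glucose or HbA1c as the
dependent trait. Only the mediator is residualized — exposure and outcome
enter unadjusted, deliberately mirroring that construction rather than a
fully covariate-adjusted mediation model.

The Sobel statistic uses the first-order standard error:

    z = a·b / sqrt(b²·s_a² + a²·s_b²)

with a, s_a from mediator ~ exposure and b, s_b the mediator coefficient
in outcome ~ exposure + mediator; p = 2·(1 − Φ(|z|)). The test is known
to be conservative under the complete null.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._regression import add_intercept, ols
from .errors import InputError
from .preprocess import MetaboliteMatrix

__all__ = [
    "MEDIATION_COVARIATES",
    "MediationResult",
    "sobel_z",
    "residualize_metabolite",
    "sobel_test",
    "run_mediation_screen",
    "mediation_intersection",
]

MEDIATION_COVARIATES = (
    "age",
    "sex",
    "physical_activity",
    "smoking",
    "systolic_bp",
    "hdl_c",
    "triglycerides",
)


@dataclass
class MediationResult:
    """Path coefficients and Sobel statistics for one mediator/trait pair."""

    metabolite: str
    trait: str
    a: float
    s_a: float
    b: float
    s_b: float
    z: float
    pvalue: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


def sobel_z(a: float, s_a: float, b: float, s_b: float) -> float:
    """First-order Sobel statistic for the indirect effect a·b."""
    denom = math.sqrt(b * b * s_a * s_a + a * a * s_b * s_b)
    if denom == 0.0:
        raise InputError("Sobel SE is zero; paths and their SEs all vanish")
    return (a * b) / denom


def residualize_metabolite(
    metabolite: pd.Series,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = MEDIATION_COVARIATES,
) -> pd.Series:
    """OLS residuals of one metabolite column on the confounder design."""
    from .associate import build_design  # local import to avoid cycle

    design = build_design(cohort, list(covariates))
    X = add_intercept(design.to_numpy(dtype=float))
    y = metabolite.to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise InputError("metabolite column and cohort have different lengths")
    beta, _, resid, _ = ols(X, y)
    return pd.Series(resid, index=metabolite.index, name=metabolite.name)


def sobel_test(
    mediator: np.ndarray | pd.Series,
    exposure: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    metabolite: str = "",
    trait: str = "",
) -> MediationResult:
    """Sobel test of whether ``mediator`` carries the exposure→outcome effect."""
    med = np.asarray(mediator, dtype=float)
    exp_ = np.asarray(exposure, dtype=float)
    out = np.asarray(outcome, dtype=float)
    if not (len(med) == len(exp_) == len(out)):
        raise InputError("mediator, exposure and outcome must have equal length")
    if len(med) < 10:
        raise InputError("need at least 10 observations for the Sobel test")
    if np.std(exp_) == 0.0 or np.std(med) == 0.0:
        raise InputError("zero-variance exposure or mediator")

    beta_a, se_a, _, _ = ols(add_intercept(exp_), med)
    a, s_a = float(beta_a[1]), float(se_a[1])
    Xb = np.column_stack([np.ones(len(out)), exp_, med])
    beta_b, se_b, _, _ = ols(Xb, out)
    b, s_b = float(beta_b[2]), float(se_b[2])

    z = sobel_z(a, s_a, b, s_b)
    p = 2.0 * float(norm.sf(abs(z)))
    return MediationResult(metabolite, trait, a, s_a, b, s_b, z, p)


def run_mediation_screen(
    metabolites: MetaboliteMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    trait: str = "fasting_glucose",
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Residualize every metabolite and Sobel-test it against BMI → trait.

    Returns one row per metabolite sorted by p, with Bonferroni q over the
    tested panel and a significance flag at q < alpha.
    """
    if trait not in ("fasting_glucose", "hba1c"):
        raise InputError(f"unknown dependent trait '{trait}'")
    data = metabolites.data if isinstance(metabolites, MetaboliteMatrix) else metabolites
    cohort_idx = (
        cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    )
    shared = data.index.intersection(cohort_idx.index)
    if len(shared) == 0:
        raise InputError("no shared participants between metabolite matrix and cohort")
    data = data.loc[shared]
    cohort_idx = cohort_idx.loc[shared]

    exposure = cohort_idx["bmi"].to_numpy(dtype=float)
    outcome = cohort_idx[trait].to_numpy(dtype=float)
    m = int(m_tests) if m_tests is not None else data.shape[1]

    rows = []
    for name in data.columns:
        resid = residualize_metabolite(data[name], cohort_idx)
        res = sobel_test(resid.to_numpy(), exposure, outcome, metabolite=name, trait=trait)
        rows.append(
            {
                "metabolite": name,
                "trait": trait,
                "a": res.a,
                "s_a": res.s_a,
                "b": res.b,
                "s_b": res.s_b,
                "z": res.z,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = np.minimum(1.0, out["pvalue"] * m)
    out["significant"] = out["qvalue"] < alpha
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def mediation_intersection(glucose: pd.DataFrame, hba1c: pd.DataFrame) -> list[str]:
    """Metabolites significant against both glycemic traits."""
    sig_glu = set(glucose.loc[glucose["significant"], "metabolite"])
    sig_hba = set(hba1c.loc[hba1c["significant"], "metabolite"])
    return sorted(sig_glu & sig_hba)
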