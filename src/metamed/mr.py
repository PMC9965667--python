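"""Bidirectional two-sample Mendelian randomization from summary statistics.

Direction 1 (BMI → metabolite): select exposure instruments at genome-wide
significance (p < 1e-8 as configured), greedily LD-clump them at r² 0.001,
harmonize against the outcome summary table, and estimate with the
inverse-variance-weighted (IVW) method; MR-Egger provides the
heterogeneity / directional-pleiotropy sensitivity analysis. Direction 2
(metabolite → T2D) uses the Wald ratio when exactly one instrument
survives, IVW otherwise; sensitivity diagnostics are skipped at one SNP.

Estimator conventions: the IVW fixed-effect estimate is the weighted
regression of outcome on exposure betas through the origin with weights
1/se_out²; Cochran's Q uses the per-SNP Wald ratios with weights
(β_exp/se_out)²; when p_Het < 0.05 the multiplicative random-effects SE,
fixed SE × √(max(1, Q/df)), is reported as primary. MR-Egger orients all
exposure betas non-negative before the free-intercept weighted regression
and uses t-distribution inference on n − 2 residual df with a
multiplicative overdispersion factor bounded below by 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, t as t_dist

from .errors import EstimatorError, InputError, InstrumentError

__all__ = [
    "HarmonizedSet",
    "MRResult",
    "select_instruments",
    "ld_clump",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "run_mr_direction",
    "run_bidirectional_mr",
]

GWAS_COLUMNS = ("SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to the same effect allele per SNP.

    ``data`` columns: SNP, beta_exp, se_exp, beta_out, se_out, action;
    ``actions`` tallies what happened to every input SNP (kept, flipped,
    dropped-palindromic, dropped-missing, dropped-irreconcilable).
    """

    data: pd.DataFrame
    actions: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.data)


@dataclass
class MRResult:
    """One causal estimate with its diagnostics."""

    method: str  # IVW-fixed | IVW-random | Wald | Egger
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    p_het: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    p_pleio: float | None = None
    random_effects: bool = False


def _validate_gwas(table: pd.DataFrame, name: str) -> None:
    missing = set(GWAS_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"{name} summary table missing columns: {sorted(missing)}")


def select_instruments(summary: pd.DataFrame, p_threshold: float = 1e-8) -> pd.DataFrame:
    """Retain rows with p strictly below the genome-wide threshold."""
    _validate_gwas(summary, "exposure")
    kept = summary[summary["pval"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        raise InstrumentError(f"no instruments at p < {p_threshold:g}")
    return kept


def ld_clump(
    instruments: pd.DataFrame, ld: pd.DataFrame, r2_threshold: float = 0.001
) -> pd.DataFrame:
    """Greedy clumping: sweep SNPs by ascending p; keep a SNP only if its
    r² with every already-kept SNP is <= threshold."""
    missing = set(instruments["SNP"]) - set(ld.index)
    if missing:
        raise InputError(f"LD matrix missing SNPs: {sorted(missing)}")
    order = instruments.sort_values("pval", kind="mergesort")
    kept: list[str] = []
    for snp in order["SNP"]:
        if all(float(ld.loc[snp, other]) <= r2_threshold for other in kept):
            kept.append(snp)
    return instruments[instruments["SNP"].isin(kept)].reset_index(drop=True)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_maf: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure effect allele.

    Swapped allele labels flip the outcome beta sign and replace EAF by
    1 − EAF. Palindromic SNPs (A/T or C/G) carry no strand information in
    their labels; they are kept (unchanged) only when both EAFs lie on the
    same side of 0.5 and both outside [maf, 1 − maf], otherwise dropped.
    Irreconcilable allele pairs are dropped with a recorded reason.
    """
    _validate_gwas(exposure, "exposure")
    _validate_gwas(outcome, "outcome")
    out_by_snp = outcome.set_index("SNP")
    rows, actions = [], []
    for rec in exposure.itertuples(index=False):
        snp = rec.SNP
        if snp not in out_by_snp.index:
            actions.append({"SNP": snp, "action": "dropped-missing"})
            continue
        orec = out_by_snp.loc[snp]
        e_ea, e_oa = str(rec.effect_allele), str(rec.other_allele)
        o_ea, o_oa = str(orec["effect_allele"]), str(orec["other_allele"])
        palindromic = frozenset((e_ea, e_oa)) in _PALINDROMIC

        if palindromic:
            if {o_ea, o_oa} != {e_ea, e_oa}:
                actions.append({"SNP": snp, "action": "dropped-irreconcilable"})
                continue
            eaf_e, eaf_o = float(rec.eaf), float(orec["eaf"])
            inside_band = (
                palindromic_maf <= eaf_e <= 1.0 - palindromic_maf
                or palindromic_maf <= eaf_o <= 1.0 - palindromic_maf
            )
            same_side = (eaf_e - 0.5) * (eaf_o - 0.5) > 0
            if inside_band or not same_side:
                actions.append({"SNP": snp, "action": "dropped-palindromic"})
                continue
            beta_out, action = float(orec["beta"]), "kept"
        elif (o_ea, o_oa) == (e_ea, e_oa):
            beta_out, action = float(orec["beta"]), "kept"
        elif (o_ea, o_oa) == (e_oa, e_ea):
            beta_out, action = -float(orec["beta"]), "flipped"
        else:
            actions.append({"SNP": snp, "action": "dropped-irreconcilable"})
            continue

        rows.append(
            {
                "SNP": snp,
                "beta_exp": float(rec.beta),
                "se_exp": float(rec.se),
                "beta_out": beta_out,
                "se_out": float(orec["se"]),
                "action": action,
            }
        )
        actions.append({"SNP": snp, "action": action})

    data = pd.DataFrame(rows, columns=["SNP", "beta_exp", "se_exp", "beta_out", "se_out", "action"])
    return HarmonizedSet(data=data, actions=pd.DataFrame(actions, columns=["SNP", "action"]))


def wald_ratio(snp: pd.Series | dict) -> MRResult:
    """Single-instrument causal estimate β_out/β_exp with the first-order
    delta-method SE se_out/|β_exp| (exposure uncertainty ignored)."""
    beta_exp = float(snp["beta_exp"])
    beta_out = float(snp["beta_out"])
    se_out = float(snp["se_out"])
    if beta_exp == 0.0:
        raise EstimatorError("Wald ratio undefined: exposure beta is zero")
    est = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    z = est / se
    half = norm.ppf(0.975) * se
    return MRResult(
        method="Wald",
        estimate=est,
        se=se,
        ci_low=est - half,
        ci_high=est + half,
        pvalue=2.0 * float(norm.sf(abs(z))),
        n_snps=1,
    )


def ivw(harmonized: HarmonizedSet) -> MRResult:
    """Inverse-variance-weighted estimate with Cochran-Q heterogeneity.

    One SNP delegates to :func:`wald_ratio`. When p_Het < 0.05 the
    multiplicative random-effects SE is reported as primary.
    """
    d = harmonized.data
    if len(d) == 0:
        raise EstimatorError("no harmonized SNPs")
    if len(d) == 1:
        return wald_ratio(d.iloc[0])
    bx = d["beta_exp"].to_numpy(dtype=float)
    by = d["beta_out"].to_numpy(dtype=float)
    so = d["se_out"].to_numpy(dtype=float)
    w = bx**2 / so**2
    est = float(np.sum(bx * by / so**2) / np.sum(w))
    se_fixed = float(math.sqrt(1.0 / np.sum(w)))
    ratios = by / bx
    q = float(np.sum(w * (ratios - est) ** 2))
    df = len(d) - 1
    p_het = float(chi2.sf(q, df))
    random_effects = p_het < 0.05
    se = se_fixed * math.sqrt(max(1.0, q / df)) if random_effects else se_fixed
    z = est / se
    half = norm.ppf(0.975) * se
    return MRResult(
        method="IVW-random" if random_effects else "IVW-fixed",
        estimate=est,
        se=se,
        ci_low=est - half,
        ci_high=est + half,
        pvalue=2.0 * float(norm.sf(abs(z))),
        n_snps=len(d),
        q_stat=q,
        q_df=df,
        p_het=p_het,
        random_effects=random_effects,
    )


def mr_egger(harmonized: HarmonizedSet) -> MRResult:
    """MR-Egger regression: slope = pleiotropy-robust causal estimate,
    intercept = directional-pleiotropy test. Needs >= 3 SNPs."""
    d = harmonized.data
    if len(d) < 3:
        raise EstimatorError("MR-Egger needs at least 3 SNPs")
    bx = d["beta_exp"].to_numpy(dtype=float)
    by = d["beta_out"].to_numpy(dtype=float)
    so = d["se_out"].to_numpy(dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / so**2
    X = np.column_stack([np.ones(len(bx)), bx])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = by * sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = len(bx) - 2
    sigma2 = max(1.0, float(resid @ resid) / df)  # multiplicative overdispersion >= 1
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))

    slope, slope_se = float(beta[1]), float(se[1])
    intercept, intercept_se = float(beta[0]), float(se[0])
    t_crit = float(t_dist.ppf(0.975, df))
    p_slope = 2.0 * float(t_dist.sf(abs(slope / slope_se), df))
    p_pleio = 2.0 * float(t_dist.sf(abs(intercept / intercept_se), df))
    return MRResult(
        method="Egger",
        estimate=slope,
        se=slope_se,
        ci_low=slope - t_crit * slope_se,
        ci_high=slope + t_crit * slope_se,
        pvalue=p_slope,
        n_snps=len(d),
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        p_pleio=p_pleio,
    )


def run_mr_direction(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    p_threshold: float = 1e-8,
    r2_threshold: float = 0.001,
) -> dict[str, MRResult | None]:
    """Select → clump → harmonize → estimate for one direction.

    Returns {"primary": MRResult, "egger": MRResult | None}; Egger is None
    when fewer than three instruments survive (as with a single-SNP Wald
    ratio, where sensitivity analysis is skipped).
    """
    instruments = select_instruments(exposure, p_threshold)
    if ld is not None:
        instruments = ld_clump(instruments, ld, r2_threshold)
    harmonized = harmonize(instruments, outcome)
    if harmonized.n_snps == 0:
        raise InstrumentError("no instruments survive harmonization")
    primary = ivw(harmonized)
    egger = mr_egger(harmonized) if harmonized.n_snps >= 3 else None
    return {"primary": primary, "egger": egger}


def run_bidirectional_mr(
    bmi_gwas: pd.DataFrame,
    metabolite_gwas: pd.DataFrame,
    t2d_gwas: pd.DataFrame,
    ld_bmi: pd.DataFrame | None = None,
    ld_metabolite: pd.DataFrame | None = None,
    p_threshold: float = 1e-8,
    r2_threshold: float = 0.001,
) -> dict[str, dict[str, MRResult | None] | None]:
    """Both causal directions for one metabolite.

    Direction 1 instruments BMI against the metabolite's GWAS; direction 2
    instruments the metabolite against the T2D GWAS. A direction with no
    usable instruments is reported as None rather than aborting the run.
    """
    results: dict[str, dict[str, MRResult | None] | None] = {}
    try:
        results["bmi_to_metabolite"] = run_mr_direction(
            bmi_gwas, metabolite_gwas, ld_bmi, p_threshold, r2_threshold
        )
    except InstrumentError:
        results["bmi_to_metabolite"] = None
    try:
        results["metabolite_to_t2d"] = run_mr_direction(
            metabolite_gwas, t2d_gwas, ld_metabolite, p_threshold, r2_threshold
        )
    except InstrumentError:
        results["metabolite_to_t2d"] = None
    return results


def results_table(results: dict[str, dict[str, MRResult | None] | None]) -> pd.DataFrame:
    """Flatten bidirectional results into the report-table shape."""
    rows = []
    for direction, res in results.items():
        if res is None:
            rows.append({"direction": direction, "method": "unavailable"})
            continue
        for key in ("primary", "egger"):
            r = res[key]
            if r is None:
                continue
            rows.append(
                {
                    "direction": direction,
                    "method": r.method,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "pvalue": r.pvalue,
                    "n_snps": r.n_snps,
                    "q_stat": r.q_stat,
                    "p_het": r.p_het,
                    "egger_intercept": r.egger_intercept,
                    "p_pleio": r.p_pleio,
                }
            )
    return pd.DataFrame(rows)
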