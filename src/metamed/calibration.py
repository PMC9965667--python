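"""Seeded Monte-Carlo calibration and recovery experiments.

These drive the package's own estimators over replicated synthetic draws:
type-I-error calibration of the Sobel screen under the complete null,
uniformity of the IVW heterogeneity p-value when no heterogeneity is
planted, detection power for a planted mediation path, and 3-SE coverage
of planted MR causal effects and Egger pleiotropy intercepts.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .mediate import sobel_test
from .mr import harmonize, ivw, mr_egger, select_instruments
from .simulate import MRTruth, SimulationConfig, generate_gwas_summaries

__all__ = [
    "sobel_null_rejection_rate",
    "ivw_phet_under_null",
    "mediation_power",
    "mr_recovery_rates",
]


def sobel_null_rejection_rate(
    n: int = 1000, reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of complete-null replicates (a = b = 0) with Sobel p < alpha.

    The Sobel test is conservative under the complete null, so this should
    come out at or below alpha.
    """
    rng = np.random.default_rng([seed, 101])
    hits = 0
    for _ in range(reps):
        x = rng.standard_normal(n)
        med = rng.standard_normal(n)
        out = rng.standard_normal(n)
        hits += sobel_test(med, x, out).pvalue < alpha
    return hits / reps


def ivw_phet_under_null(
    n_instruments: int = 50, reps: int = 500, seed: int = 0, causal: float = 0.2
) -> np.ndarray:
    """Cochran-Q heterogeneity p-values over replicates with no planted
    heterogeneity; should be approximately Uniform(0, 1)."""
    pvals = np.empty(reps)
    for r in range(reps):
        cfg = SimulationConfig(
            seed=seed * reps + r,
            mr_truth=MRTruth(n_instruments, causal, 0.0, 0.0),
            mr_palindromic_fraction=0.0,
        )
        exp, out, _ = generate_gwas_summaries(cfg)
        res = ivw(harmonize(select_instruments(exp), out))
        pvals[r] = res.p_het
    return pvals


def mediation_power(
    a: float = 0.3,
    b: float = 0.3,
    n: int = 2000,
    reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    m_tests: int = 146,
) -> float:
    """Detection power for a planted standardized mediation path at the
    Bonferroni threshold alpha/m_tests."""
    rng = np.random.default_rng([seed, 202])
    threshold = alpha / m_tests
    hits = 0
    for _ in range(reps):
        x = rng.standard_normal(n)
        med = a * x + rng.standard_normal(n)
        out = b * med + rng.standard_normal(n)
        hits += sobel_test(med, x, out).pvalue < threshold
    return hits / reps


def mr_recovery_rates(
    reps: int = 200,
    seed: int = 0,
    n_instruments: int = 50,
    causal: float = 0.2,
    pleiotropy: float = 0.05,
) -> tuple[float, float]:
    """3-SE coverage of the planted causal effect (IVW) and pleiotropy
    intercept (MR-Egger) over seeded replicates."""
    causal_hits = 0
    intercept_hits = 0
    for r in range(reps):
        cfg = SimulationConfig(
            seed=seed * reps + r,
            mr_truth=MRTruth(n_instruments, causal, 0.0, 0.0),
            mr_palindromic_fraction=0.0,
        )
        exp, out, _ = generate_gwas_summaries(cfg)
        h = harmonize(select_instruments(exp), out)
        res = ivw(h)
        causal_hits += abs(res.estimate - causal) < 3 * res.se

        cfg_p = dataclasses.replace(
            cfg, mr_truth=MRTruth(n_instruments, causal, 0.0, pleiotropy)
        )
        exp_p, out_p, _ = generate_gwas_summaries(cfg_p)
        egger = mr_egger(harmonize(select_instruments(exp_p), out_p))
        intercept_hits += (
            abs(egger.egger_intercept - pleiotropy) < 3 * egger.egger_intercept_se
        )
    return causal_hits / reps, intercept_hits / reps
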