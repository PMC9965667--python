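"""Seeded synthetic data: cohort, plate-structured metabolite matrices, GWAS summaries.

The generator emulates the study conditions of a ~1715-participant
population-based cohort with targeted serum metabolomics on multi-plate
kit runs, a configurable BMI → metabolite → glycemia mediation structure,
type-2-diabetes status assigned through a logistic link, and paired
exposure/outcome GWAS summary-statistics tables with known causal effect,
heterogeneity and directional pleiotropy. Every artifact records its
ground truth so downstream estimators can be tested for parameter
recovery without any external data.

Randomness discipline: one independent RNG stream per artifact (cohort,
plates, GWAS), derived from the master seed by a fixed offset, so
regenerating one artifact never perturbs another.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InputError

__all__ = [
    "SimulationConfig",
    "MediationTruth",
    "MRTruth",
    "TruthRecord",
    "RawPlateMatrix",
    "generate_cohort",
    "generate_metabolite_plates",
    "generate_gwas_summaries",
    "identity_ld",
    "block_ld",
]

# Fixed per-artifact RNG stream offsets.
_STREAM_COHORT = 0
_STREAM_PLATES = 1
_STREAM_GWAS = 2

#: covariates every regression model may request; a missing value in any of
#: them puts a participant into exclusion rule 1.
MODEL_COVARIATES = (
    "age",
    "sex",
    "smoking",
    "physical_activity",
    "systolic_bp",
    "hdl_c",
    "triglycerides",
    "fasting_glucose",
    "hba1c",
    "bmi",
)

DIABETES_CLASSES = ("none", "prediabetes", "T1D", "T2D", "unclear")
EXCLUSION_CLASSES = ("underweight_missing", "prediabetes", "T1D", "unclear")

_BMI_MEAN = 27.5
_BMI_SD = 4.7
_GLUCOSE_MEAN = 5.5  # mmol/L, roughly the non-diabetic cohort mean


@dataclass(frozen=True)
class MediationTruth:
    """Planted mediation pathway for one metabolite.

    ``a`` is the BMI→metabolite slope in SD of log-metabolite per kg/m²;
    ``b`` is the metabolite→glycemia slope in mmol/L per SD.
    """

    metabolite: int
    a: float
    b: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class MRTruth:
    """Planted instrument-level truth for one GWAS summary pair."""

    n_instruments: int = 50
    causal_effect: float = 0.2
    heterogeneity_sd: float = 0.0
    pleiotropy_intercept: float = 0.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults follow the emulated cohort: ~1715 analysis participants, 146
    metabolites measured on 22 kit plates (each carrying three zero-sample
    rows and reference rows, five reference measurements per metabolite
    across the run), age ~ Normal(59, 12), BMI log-normal with mean 27.5
    and SD 4.7 kg/m², T2D prevalence ≈ 0.17 via the logistic link.
    """

    n_participants: int = 1715
    n_metabolites: int = 146
    n_plates: int = 22
    seed: int = 0

    # BMI → metabolite → glycemia structure ---------------------------------
    mediation_truths: tuple[MediationTruth, ...] = (
        MediationTruth(0, 0.05, 0.10),
        MediationTruth(1, 0.04, 0.08),
        MediationTruth(2, 0.04, 0.06),
    )
    direct_effect: float = 0.04  # mmol/L fasting glucose per kg/m², bypassing mediators
    glucose_noise_sd: float = 0.9  # mmol/L
    t2d_intercept: float = -10.2
    t2d_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"fasting_glucose": 1.1, "bmi": 0.08}
    )

    # plate / assay structure ----------------------------------------------
    censor_fraction: float = 0.05
    metabolite_log_sd: float = 0.4
    reference_cv: float = 0.05
    zero_noise_scale: float = 0.01
    plate_batch_sd: float = 0.1
    plate_batch_factors: Sequence[float] | None = None

    # planted QC violations (metabolite indices)
    cv_violation_metabolites: tuple[int, ...] = ()
    lod_violation_metabolites: tuple[int, ...] = ()
    nd_violation_metabolites: tuple[int, ...] = ()
    nd_violation_fraction: float = 0.6

    # exclusion-filter plants ----------------------------------------------
    class_fractions: Mapping[str, float] = field(default_factory=dict)
    class_counts: Mapping[str, int] | None = None

    # GWAS summary pair ----------------------------------------------------
    mr_truth: MRTruth = MRTruth()
    mr_swap_fraction: float = 0.2
    mr_palindromic_fraction: float = 0.1
    mr_outcome_se: float = 0.01

    def validate(self) -> None:
        for name in ("n_participants", "n_metabolites", "n_plates"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ConfigurationError("censor_fraction must lie in [0, 1)")
        if self.nd_violation_metabolites and not 0.5 <= self.nd_violation_fraction < 1.0:
            raise ConfigurationError("nd_violation_fraction must lie in [0.5, 1)")
        fracs = dict(self.class_fractions)
        unknown = set(fracs) - set(EXCLUSION_CLASSES)
        if unknown:
            raise ConfigurationError(f"class_fractions has unknown classes: {sorted(unknown)}")
        if any(v < 0 for v in fracs.values()) or sum(fracs.values()) >= 1.0:
            raise ConfigurationError("class_fractions must be nonnegative and sum to < 1")
        if self.class_counts is not None:
            unknown = set(self.class_counts) - set(EXCLUSION_CLASSES)
            if unknown:
                raise ConfigurationError(f"class_counts has unknown classes: {sorted(unknown)}")
            if sum(self.class_counts.values()) >= self.n_participants:
                raise ConfigurationError("class_counts must leave at least one unplanted participant")
        for truth in self.mediation_truths:
            if not 0 <= truth.metabolite < self.n_metabolites:
                raise ConfigurationError(
                    f"mediation_truths metabolite index {truth.metabolite} out of range"
                )
        if self.mr_truth.n_instruments < 1:
            raise ConfigurationError("mr_truth.n_instruments must be >= 1")
        if not 0.0 <= self.mr_swap_fraction <= 1.0:
            raise ConfigurationError("mr_swap_fraction must lie in [0, 1]")
        if not 0.0 <= self.mr_palindromic_fraction <= 1.0:
            raise ConfigurationError("mr_palindromic_fraction must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthRecord:
    """Ground truth drawn by the generator; round-trips through JSON exactly."""

    seed: int
    direct_effect: float = 0.0
    mediation: tuple[MediationTruth, ...] = ()
    mr: MRTruth | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "direct_effect": self.direct_effect,
            "mediation": [
                {"metabolite": t.metabolite, "a": t.a, "b": t.b, "indirect": t.indirect}
                for t in self.mediation
            ],
            "mr": None if self.mr is None else dataclasses.asdict(self.mr),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        payload = json.loads(text)
        return cls(
            seed=payload["seed"],
            direct_effect=payload["direct_effect"],
            mediation=tuple(
                MediationTruth(m["metabolite"], m["a"], m["b"]) for m in payload["mediation"]
            ),
            mr=None if payload["mr"] is None else MRTruth(**payload["mr"]),
        )


@dataclass
class RawPlateMatrix:
    """Plate-structured raw concentrations (µM) with per-cell detectability.

    ``data`` has one row per physical well: columns ``plate``, ``role``
    (zero / reference / sample), ``participant_id`` (sample rows only) and
    one column per metabolite. ``nondetect`` is a boolean frame aligned to
    the metabolite columns; a True cell has no measured value (NaN in
    ``data``). ``imputed`` is filled by the preprocessing stage.
    """

    data: pd.DataFrame
    nondetect: pd.DataFrame
    imputed: pd.DataFrame | None = None

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("met_")]

    def sample_rows(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "sample"]

    def copy(self) -> "RawPlateMatrix":
        return RawPlateMatrix(
            self.data.copy(),
            self.nondetect.copy(),
            None if self.imputed is None else self.imputed.copy(),
        )


def metabolite_name(index: int) -> str:
    return f"met_{index:03d}"


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one cohort table plus its truth record.

    Fasting glucose is built as
    ``5.5 + direct_effect·(BMI − 27.5) + Σ_j b_j·z_j + noise`` where each
    mediator's latent standardized log-abundance ``z_j = a_j·(BMI − 27.5) + ε``
    is stored in a hidden ``_met_*_z`` column so the plate generator can emit
    concentrations consistent with the glycemia the cohort already carries.
    """
    config.validate()
    rng = config.rng(_STREAM_COHORT)
    n = config.n_participants

    age = np.clip(rng.normal(59.0, 12.0, n), 25.0, 95.0)
    sex = np.where(rng.random(n) < 0.527, "woman", "man")

    sigma = math.sqrt(math.log1p((_BMI_SD / _BMI_MEAN) ** 2))
    mu = math.log(_BMI_MEAN) - sigma**2 / 2.0
    # clip at 16 so the underweight exclusion class is exactly the planted set
    bmi = np.clip(rng.lognormal(mu, sigma, n), 16.0, None)

    smoking = rng.choice(["smoker", "ex-smoker", "never"], size=n, p=[0.156, 0.384, 0.460])
    p_inactive = expit(-0.37 + 0.08 * (bmi - _BMI_MEAN))
    physical_activity = np.where(rng.random(n) < p_inactive, "inactive", "active")

    systolic_bp = 118.0 + 0.55 * (bmi - _BMI_MEAN) + rng.normal(0.0, 16.0, n)
    hdl_c = np.clip(1.72 - 0.025 * (bmi - _BMI_MEAN) + rng.normal(0.0, 0.42, n), 0.4, None)
    triglycerides = np.exp(math.log(1.25) + 0.02 * (bmi - _BMI_MEAN) + rng.normal(0.0, 0.45, n))
    alcohol = rng.gamma(shape=0.8, scale=17.75, size=n)

    latents: dict[int, np.ndarray] = {}
    glucose = _GLUCOSE_MEAN + config.direct_effect * (bmi - _BMI_MEAN)
    for truth in config.mediation_truths:
        z = truth.a * (bmi - _BMI_MEAN) + rng.standard_normal(n)
        latents[truth.metabolite] = z
        glucose = glucose + truth.b * z
    glucose = np.clip(glucose + rng.normal(0.0, config.glucose_noise_sd, n), 3.0, None)
    hba1c = np.clip(5.5 + 0.45 * (glucose - _GLUCOSE_MEAN) + rng.normal(0.0, 0.25, n), 3.5, None)

    lp = np.full(n, float(config.t2d_intercept))
    trait_map = {"fasting_glucose": glucose, "bmi": bmi, "hba1c": hba1c, "age": age}
    for name, coef in config.t2d_coefficients.items():
        if name not in trait_map:
            raise ConfigurationError(f"t2d_coefficients references unknown trait '{name}'")
        lp = lp + coef * trait_map[name]
    t2d_draw = rng.random(n) < expit(lp)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "physical_activity": physical_activity,
            "systolic_bp": systolic_bp,
            "hdl_c": hdl_c,
            "triglycerides": triglycerides,
            "fasting_glucose": glucose,
            "hba1c": hba1c,
            "bmi": bmi,
            "alcohol": alcohol,
        }
    )
    cohort["diabetes_class"] = np.where(t2d_draw, "T2D", "none")

    _plant_exclusion_classes(cohort, config, rng)
    cohort["t2d"] = (cohort["diabetes_class"] == "T2D").astype(int)

    for idx, z in latents.items():
        cohort[f"_{metabolite_name(idx)}_z"] = z

    truth = TruthRecord(
        seed=config.seed,
        direct_effect=config.direct_effect,
        mediation=tuple(config.mediation_truths),
    )
    return cohort, truth


def _plant_exclusion_classes(
    cohort: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> None:
    n = len(cohort)
    if config.class_counts is not None:
        counts = {c: int(config.class_counts.get(c, 0)) for c in EXCLUSION_CLASSES}
    else:
        counts = {c: int(round(config.class_fractions.get(c, 0.0) * n)) for c in EXCLUSION_CLASSES}
    total = sum(counts.values())
    if total == 0:
        return
    if total >= n:
        raise ConfigurationError("planted exclusion classes exceed cohort size")
    chosen = rng.choice(n, size=total, replace=False)
    start = 0
    for cls in EXCLUSION_CLASSES:
        rows = chosen[start : start + counts[cls]]
        start += counts[cls]
        if len(rows) == 0:
            continue
        if cls == "underweight_missing":
            # half get an underweight BMI, half a missing lipid covariate
            half = len(rows) // 2
            cohort.loc[cohort.index[rows[:half]], "bmi"] = rng.uniform(13.0, 14.9, half)
            cohort.loc[cohort.index[rows[half:]], "hdl_c"] = np.nan
        else:
            cohort.loc[cohort.index[rows], "diabetes_class"] = cls


# ---------------------------------------------------------------------------
# plates


def generate_metabolite_plates(config: SimulationConfig, cohort: pd.DataFrame) -> RawPlateMatrix:
    """Lay the cohort out on kit plates and draw raw concentrations.

    Each metabolite's log-concentration is ``log(base) + σ·z`` with z
    standard normal except for planted mediators, whose latent z (shifted
    by a·BMI) is taken from the cohort's hidden columns. A multiplicative
    per-plate batch factor is applied; values below the metabolite's
    censoring quantile are flagged non-detectable and withheld.
    """
    config.validate()
    if len(cohort) != config.n_participants:
        raise InputError(
            f"cohort has {len(cohort)} rows but config.n_participants={config.n_participants}"
        )
    rng = config.rng(_STREAM_PLATES)
    n, m = config.n_participants, config.n_metabolites
    met_cols = [metabolite_name(j) for j in range(m)]

    base = np.exp(rng.uniform(math.log(0.5), math.log(50.0), m))
    if config.plate_batch_factors is not None:
        if len(config.plate_batch_factors) != config.n_plates:
            raise ConfigurationError("plate_batch_factors length must equal n_plates")
        batch = np.asarray(config.plate_batch_factors, dtype=float)
    else:
        batch = rng.lognormal(0.0, config.plate_batch_sd, config.n_plates)

    z = rng.standard_normal((n, m))
    for truth in config.mediation_truths:
        col = f"_{metabolite_name(truth.metabolite)}_z"
        if col in cohort.columns:
            z[:, truth.metabolite] = cohort[col].to_numpy(dtype=float)

    plate_of = np.repeat(np.arange(config.n_plates), _chunk_sizes(n, config.n_plates))
    conc = base[None, :] * np.exp(config.metabolite_log_sd * z) * batch[plate_of, None]

    # censoring thresholds: per-metabolite empirical quantile of sample values
    censor = np.full(m, config.censor_fraction)
    censor[list(config.nd_violation_metabolites)] = config.nd_violation_fraction
    nd_mask = np.zeros((n, m), dtype=bool)
    for j in range(m):
        if censor[j] > 0:
            thr = np.quantile(conc[:, j], censor[j])
            nd_mask[:, j] = conc[:, j] < thr

    rows: list[pd.DataFrame] = []
    nd_rows: list[np.ndarray] = []
    ref_per_plate = _reference_counts(config.n_plates)
    start = 0
    for p, size in enumerate(_chunk_sizes(n, config.n_plates)):
        zero_vals = np.empty((3, m))
        for j in range(m):
            if j in config.lod_violation_metabolites:
                zero_vals[:, j] = base[j] * rng.uniform(0.4, 0.6, 3)
            else:
                zero_vals[:, j] = base[j] * config.zero_noise_scale * np.abs(rng.standard_normal(3))
        n_ref = ref_per_plate[p]
        ref_vals = np.empty((n_ref, m))
        for j in range(m):
            if j in config.cv_violation_metabolites:
                signs = np.where(np.arange(n_ref) % 2 == 0, 1.0, -1.0)
                ref_vals[:, j] = base[j] * np.clip(1.0 + 0.6 * signs + rng.normal(0, 0.05, n_ref), 0.05, None)
            else:
                ref_vals[:, j] = base[j] * np.clip(1.0 + rng.normal(0, config.reference_cv, n_ref), 0.05, None)
        # the batch effect acts on every well of the plate, reference and
        # zero rows included — that is what makes reference bridging work
        zero_vals *= batch[p]
        ref_vals *= batch[p]

        sample_vals = conc[start : start + size].copy()
        sample_nd = nd_mask[start : start + size]
        sample_vals[sample_nd] = np.nan
        pid = cohort["participant_id"].to_numpy()[start : start + size]
        start += size

        block_vals = np.vstack([zero_vals, ref_vals, sample_vals])
        block = pd.DataFrame(block_vals, columns=met_cols)
        block.insert(0, "participant_id", [""] * (3 + n_ref) + list(pid))
        block.insert(0, "role", ["zero"] * 3 + ["reference"] * n_ref + ["sample"] * size)
        block.insert(0, "plate", p)
        rows.append(block)
        nd_rows.append(
            np.vstack([np.zeros((3 + n_ref, m), dtype=bool), sample_nd])
        )

    data = pd.concat(rows, ignore_index=True)
    nondetect = pd.DataFrame(np.vstack(nd_rows), columns=met_cols)
    return RawPlateMatrix(data=data, nondetect=nondetect)


def _chunk_sizes(n: int, k: int) -> list[int]:
    q, r = divmod(n, k)
    return [q + (1 if i < r else 0) for i in range(k)]


def _reference_counts(n_plates: int) -> list[int]:
    """One reference row per plate, topped up so the run carries >= 5."""
    counts = [1] * n_plates
    i = 0
    while sum(counts) < 5:
        counts[i % n_plates] += 1
        i += 1
    return counts


# ---------------------------------------------------------------------------
# GWAS summaries

_NON_PALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


def generate_gwas_summaries(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw one exposure/outcome GWAS summary-statistics pair.

    Instruments are emitted oriented to the trait-increasing allele
    (exposure betas > 0, the convention of published instrument lists), so
    a planted directional-pleiotropy intercept keeps one sign. Outcome
    betas are ``causal·β_exp + intercept + Normal(0, het_sd)`` plus
    estimation noise at the stated SE. A configured fraction of outcome
    rows is emitted with swapped alleles (sign and EAF flipped — the same
    association stated the other way round) and a fraction of SNPs is
    palindromic, to exercise harmonization.
    """
    config.validate()
    truth = config.mr_truth
    rng = config.rng(_STREAM_GWAS)
    k = truth.n_instruments

    snp = [f"rs{i + 1:06d}" for i in range(k)]
    n_pal = int(round(config.mr_palindromic_fraction * k))
    pal_flags = np.zeros(k, dtype=bool)
    pal_flags[:n_pal] = True
    alleles = []
    for i in range(k):
        pool = _PALINDROMIC_PAIRS if pal_flags[i] else _NON_PALINDROMIC_PAIRS
        ea, oa = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            ea, oa = oa, ea
        alleles.append((ea, oa))
    eaf = rng.uniform(0.05, 0.95, k)

    beta_exp = rng.uniform(0.05, 0.15, k)
    z_exp = rng.uniform(7.0, 18.0, k)
    se_exp = beta_exp / z_exp
    p_exp = 2.0 * _norm_sf(np.abs(beta_exp / se_exp))

    se_out = np.full(k, float(config.mr_outcome_se))
    beta_out = (
        truth.causal_effect * beta_exp
        + truth.pleiotropy_intercept
        + rng.normal(0.0, truth.heterogeneity_sd, k)
        + rng.normal(0.0, se_out)
    )
    p_out = 2.0 * _norm_sf(np.abs(beta_out / se_out))

    exposure = pd.DataFrame(
        {
            "SNP": snp,
            "effect_allele": [a[0] for a in alleles],
            "other_allele": [a[1] for a in alleles],
            "eaf": eaf,
            "beta": beta_exp,
            "se": se_exp,
            "pval": p_exp,
        }
    )

    swap = rng.random(k) < config.mr_swap_fraction
    out_ea = np.where(swap, [a[1] for a in alleles], [a[0] for a in alleles])
    out_oa = np.where(swap, [a[0] for a in alleles], [a[1] for a in alleles])
    outcome = pd.DataFrame(
        {
            "SNP": snp,
            "effect_allele": out_ea,
            "other_allele": out_oa,
            "eaf": np.where(swap, 1.0 - eaf, eaf),
            "beta": np.where(swap, -beta_out, beta_out),
            "se": se_out,
            "pval": p_out,
        }
    )

    record = TruthRecord(seed=config.seed, mr=truth)
    return exposure, outcome, record


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(z)


def identity_ld(snps: Sequence[str]) -> pd.DataFrame:
    """r² matrix for mutually independent variants."""
    eye = np.eye(len(snps))
    return pd.DataFrame(eye, index=list(snps), columns=list(snps))


def block_ld(snps: Sequence[str], blocks: Sequence[Sequence[str]], r2: float = 0.9) -> pd.DataFrame:
    """r² matrix with the given blocks mutually correlated at ``r2``."""
    ld = identity_ld(snps)
    for block in blocks:
        for a in block:
            for b in block:
                if a != b:
                    ld.loc[a, b] = r2
    return ld
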