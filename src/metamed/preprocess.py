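"""Participant exclusions and metabolite QC / imputation / normalization.

The cohort filter removes, in order: (1) underweight (BMI < 15 kg/m²) or
any missing model covariate, (2) prediabetes, (3) type-1 diabetes,
(4) unclear diabetes type; a participant is tallied once, under the first
matching rule.

Metabolite QC applies three exclusion criteria, any one of which deletes
a metabolite from the panel:

1. CV of the reference-sample measurements >= 25% (sample SD / mean);
2. >= 50% of all measured sample concentrations below their own plate's
   limit of detection, where the plate LOD is 3 x the median of that
   plate's three zero (blank) samples;
3. non-detectable rate across all sample cells >= 50%.

Non-detectable cells of retained metabolites are imputed uniformly on
[0.75, 1.25] x (half of the plate's minimum measured value); plate batch
effects are removed with reference-sample bridging factors
NF(plate, metabolite) = global reference median / plate reference median;
finally each metabolite column is natural-log transformed and
standardized to mean 0, SD 1 on the analysis sample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ImputationError,
    InputError,
    NormalizationError,
    TransformError,
)
from .simulate import DIABETES_CLASSES, MODEL_COVARIATES, RawPlateMatrix

__all__ = [
    "QCReport",
    "MetaboliteMatrix",
    "filter_participants",
    "compute_plate_lod",
    "lod_table",
    "apply_exclusion_criteria",
    "impute_nondetectable",
    "plate_normalize",
    "log_scale_transform",
    "preprocess_plates",
    "CV_THRESHOLD",
    "BELOW_LOD_THRESHOLD",
    "ND_THRESHOLD",
]

CV_THRESHOLD = 0.25
BELOW_LOD_THRESHOLD = 0.50
ND_THRESHOLD = 0.50

EXCLUSION_RULES = (
    "underweight_or_missing",
    "prediabetes",
    "T1D",
    "unclear",
)


@dataclass
class QCReport:
    """Per-metabolite QC metrics plus per-plate LODs and normalization factors.

    ``metabolite`` is indexed by metabolite name with columns ``cv``,
    ``frac_below_lod``, ``frac_nondetect``, ``excluded`` and ``reason``
    (comma-joined subset of {CV, LOD, ND}). ``lod`` and ``nf`` are
    plate x metabolite frames; ``nf`` is filled by :func:`plate_normalize`.
    """

    metabolite: pd.DataFrame
    lod: pd.DataFrame
    nf: pd.DataFrame | None = None

    @property
    def retained(self) -> list[str]:
        return list(self.metabolite.index[~self.metabolite["excluded"]])

    @property
    def excluded(self) -> list[str]:
        return list(self.metabolite.index[self.metabolite["excluded"]])


@dataclass
class MetaboliteMatrix:
    """Analysis-ready participants x metabolites matrix.

    ``data`` holds natural-log transformed, standardized values indexed by
    participant id; ``center``/``scale`` store the per-column log-scale
    mean and sample SD so the transform is invertible; ``imputed`` flags
    cells whose raw value was drawn by the below-LOD imputation.
    """

    data: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    imputed: pd.DataFrame


# ---------------------------------------------------------------------------
# participants


def filter_participants(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four exclusion rules in order; first match wins."""
    labels = set(cohort["diabetes_class"].unique())
    unknown = labels - set(DIABETES_CLASSES)
    if unknown:
        raise InputError(f"unknown diabetes_class labels: {sorted(unknown)}")

    covars = [c for c in MODEL_COVARIATES if c in cohort.columns]
    missing_cov = cohort[covars].isna().any(axis=1)
    rule1 = (cohort["bmi"] < 15.0) | cohort["bmi"].isna() | missing_cov
    rule2 = (cohort["diabetes_class"] == "prediabetes") & ~rule1
    rule3 = (cohort["diabetes_class"] == "T1D") & ~rule1 & ~rule2
    rule4 = (cohort["diabetes_class"] == "unclear") & ~rule1 & ~rule2 & ~rule3

    tally = {
        "underweight_or_missing": int(rule1.sum()),
        "prediabetes": int(rule2.sum()),
        "T1D": int(rule3.sum()),
        "unclear": int(rule4.sum()),
    }
    tally["total_excluded"] = sum(tally.values())
    survivors = cohort[~(rule1 | rule2 | rule3 | rule4)].reset_index(drop=True)
    return survivors, tally


# ---------------------------------------------------------------------------
# metabolite QC


def compute_plate_lod(plates: RawPlateMatrix, plate: int, metabolite: str) -> float:
    """Plate limit of detection: 3 x median of the plate's zero samples."""
    mask = (plates.data["plate"] == plate) & (plates.data["role"] == "zero")
    vals = plates.data.loc[mask, metabolite].dropna().to_numpy(dtype=float)
    if len(vals) < 3:
        raise InputError(
            f"plate {plate} has {len(vals)} zero-sample values for {metabolite}; need >= 3"
        )
    return 3.0 * float(np.median(vals))


def lod_table(plates: RawPlateMatrix) -> pd.DataFrame:
    mets = plates.metabolites
    plate_ids = sorted(plates.data["plate"].unique())
    out = pd.DataFrame(index=plate_ids, columns=mets, dtype=float)
    for p in plate_ids:
        for m in mets:
            out.loc[p, m] = compute_plate_lod(plates, p, m)
    return out


def apply_exclusion_criteria(plates: RawPlateMatrix) -> QCReport:
    """Evaluate the three exclusion criteria for every metabolite.

    A reference mean of zero leaves the CV undefined; such a metabolite is
    excluded with reason CV rather than raising.
    """
    mets = plates.metabolites
    data = plates.data
    ref = data[data["role"] == "reference"]
    if ref.empty:
        raise InputError("no reference rows present")
    samp_mask = data["role"] == "sample"
    samples = data[samp_mask]
    lods = lod_table(plates)

    records = []
    for m in mets:
        ref_vals = ref[m].dropna().to_numpy(dtype=float)
        mean = ref_vals.mean() if len(ref_vals) else 0.0
        if len(ref_vals) < 2 or mean == 0.0:
            cv = np.nan
            cv_fires = True  # undefined CV counts as failing criterion 1
        else:
            cv = float(np.std(ref_vals, ddof=1) / mean)
            cv_fires = cv >= CV_THRESHOLD

        vals = samples[m].to_numpy(dtype=float)
        nd = plates.nondetect.loc[samples.index, m].to_numpy(dtype=bool)
        measured = vals[~nd]
        if len(measured):
            per_lod = lods.loc[samples["plate"], m].to_numpy(dtype=float)[~nd]
            frac_below = float(np.mean(measured < per_lod))
        else:
            frac_below = 0.0
        frac_nd = float(np.mean(nd)) if len(nd) else 0.0

        lod_fires = frac_below >= BELOW_LOD_THRESHOLD
        nd_fires = frac_nd >= ND_THRESHOLD
        reasons = [
            name
            for name, fired in (("CV", cv_fires), ("LOD", lod_fires), ("ND", nd_fires))
            if fired
        ]
        records.append(
            {
                "metabolite": m,
                "cv": cv,
                "frac_below_lod": frac_below,
                "frac_nondetect": frac_nd,
                "excluded": bool(reasons),
                "reason": ",".join(reasons),
            }
        )
    table = pd.DataFrame(records).set_index("metabolite")
    return QCReport(metabolite=table, lod=lods)


def impute_nondetectable(
    plates: RawPlateMatrix, qc: QCReport, seed: int
) -> RawPlateMatrix:
    """Replace non-detectable cells of retained metabolites.

    Each ND cell gets Uniform(0.75, 1.25) x (half of the plate minimum
    measured value for that metabolite); measured cells pass through
    bit-exact. Excluded metabolites are dropped from the output.
    """
    rng = np.random.default_rng(seed)
    retained = qc.retained
    out = plates.copy()
    keep_cols = [c for c in out.data.columns if not c.startswith("met_")] + retained
    out.data = out.data[keep_cols]
    out.nondetect = out.nondetect[retained]
    imputed = pd.DataFrame(False, index=out.data.index, columns=retained)

    samp_mask = out.data["role"] == "sample"
    for m in retained:
        nd_col = out.nondetect[m] & samp_mask
        if not nd_col.any():
            continue
        for p, block in out.data[samp_mask].groupby("plate"):
            idx = block.index[out.nondetect.loc[block.index, m]]
            if len(idx) == 0:
                continue
            measured = block.loc[~out.nondetect.loc[block.index, m], m].dropna()
            if measured.empty:
                raise ImputationError(
                    f"plate {p} has no measured values for {m}; cannot impute"
                )
            half_min = 0.5 * float(measured.min())
            draws = rng.uniform(0.75, 1.25, len(idx)) * half_min
            out.data.loc[idx, m] = draws
            out.nondetect.loc[idx, m] = False
            imputed.loc[idx, m] = True
    out.imputed = imputed
    return out


def plate_normalize(plates: RawPlateMatrix, qc: QCReport) -> RawPlateMatrix:
    """Reference-sample bridging: scale each plate so its reference median
    matches the across-plate reference median, per metabolite."""
    mets = [m for m in plates.metabolites]
    data = plates.data
    ref = data[data["role"] == "reference"]
    if ref.empty:
        raise InputError("no reference rows present")
    plate_ids = sorted(data["plate"].unique())
    nf = pd.DataFrame(index=plate_ids, columns=mets, dtype=float)
    out = plates.copy()
    for m in mets:
        global_median = float(ref[m].median())
        for p in plate_ids:
            plate_median = float(ref.loc[ref["plate"] == p, m].median())
            if plate_median == 0.0 or np.isnan(plate_median):
                raise NormalizationError(
                    f"plate {p} reference median is zero/undefined for {m}"
                )
            nf.loc[p, m] = global_median / plate_median
    samp = out.data["role"] == "sample"
    for m in mets:
        factors = nf.loc[out.data.loc[samp, "plate"], m].to_numpy(dtype=float)
        out.data.loc[samp, m] = out.data.loc[samp, m].to_numpy(dtype=float) * factors
    qc.nf = nf
    return out


def log_scale_transform(plates: RawPlateMatrix) -> MetaboliteMatrix:
    """Natural-log then z-score each metabolite on the analysis sample.

    Uses the sample (n-1) SD; raises on nonpositive values (naming the
    offending cell) and on zero-variance columns.
    """
    mets = plates.metabolites
    samples = plates.sample_rows()
    mat = samples[mets].astype(float)
    mat.index = samples["participant_id"].to_numpy()

    bad = mat.le(0) | mat.isna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = bad.index[bad[col]][0]
        raise TransformError(f"nonpositive or missing value at participant {row}, {col}")

    logged = np.log(mat)
    center = logged.mean()
    scale = logged.std(ddof=1)
    flat = scale[scale == 0.0]
    if len(flat):
        raise TransformError(f"zero-variance column after log transform: {flat.index[0]}")
    data = (logged - center) / scale

    if plates.imputed is not None:
        imputed = plates.imputed.loc[samples.index, mets].copy()
        imputed.index = mat.index
    else:
        imputed = pd.DataFrame(False, index=mat.index, columns=mets)
    return MetaboliteMatrix(data=data, center=center, scale=scale, imputed=imputed)


def preprocess_plates(plates: RawPlateMatrix, seed: int = 0) -> tuple[MetaboliteMatrix, QCReport]:
    """QC -> imputation -> plate normalization -> log/scale, in order."""
    qc = apply_exclusion_criteria(plates)
    imputed = impute_nondetectable(plates, qc, seed=seed)
    normalized = plate_normalize(imputed, qc)
    matrix = log_scale_transform(normalized)
    return matrix, qc
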