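"""End-to-end orchestration: simulate → preprocess → associate → mediate → MR.

Each enabled stage writes its report tables under the output directory and
records SHA-256 digests in a run manifest, so identical config + seed
reproduces identical digests. A stage failure halts the run with a
stage-named error; completed outputs are preserved.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .associate import ModelSpec, bonferroni_adjust, fit_linear_assoc, fit_logistic_assoc, model_staircase
from .errors import DependencyError, SummaryError
from .mediate import mediation_intersection, run_mediation_screen
from .mr import results_table, run_bidirectional_mr
from .preprocess import filter_participants, preprocess_plates
from .simulate import (
    MRTruth,
    SimulationConfig,
    generate_cohort,
    generate_gwas_summaries,
    generate_metabolite_plates,
    identity_ld,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "summarize_cohort"]

STAGES = ("simulate", "preprocess", "associate", "mediate", "mr")

_CONTINUOUS_VARS = (
    "age",
    "bmi",
    "systolic_bp",
    "hdl_c",
    "triglycerides",
    "fasting_glucose",
    "hba1c",
    "alcohol",
)
_CATEGORICAL_VARS = ("sex", "smoking", "physical_activity")


@dataclass
class RunConfig:
    """Settings for one pipeline run; round-trips through YAML/JSON."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "metamed_run"
    alpha: float = 0.05
    m_tests: int | None = None
    stages: tuple[str, ...] = STAGES
    #: direction-2 (metabolite → T2D) planted truth; one instrument by default,
    #: which exercises the single-SNP Wald-ratio path.
    mr_truth_secondary: MRTruth = MRTruth(n_instruments=1, causal_effect=0.3)

    def validate(self) -> None:
        self.simulation.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise DependencyError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunManifest:
    """Per-stage output digests plus a config snapshot."""

    config: dict
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages, "skipped": self.skipped},
            indent=2,
            default=str,
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: RunManifest, stage: str, paths: list[Path]) -> None:
    manifest.stages[stage] = {p.name: _digest(p) for p in sorted(paths)}


def run_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config))
    sim = config.simulation

    cohort = plates = matrix = None
    for stage in STAGES:
        if stage not in config.stages:
            manifest.skipped.append(stage)
            continue
        if stage == "simulate":
            cohort, truth = generate_cohort(sim)
            plates = generate_metabolite_plates(sim, cohort)
            paths = [mio.write_cohort(cohort, outdir / "cohort.csv")]
            paths += mio.write_plates(plates, outdir / "plates")
            paths.append(mio.write_truth(truth, outdir / "truth.json"))
            _record(manifest, stage, paths)
        elif stage == "preprocess":
            _require(cohort is not None and plates is not None, stage)
            cohort, tally = filter_participants(cohort)
            plates_f = _restrict_plates(plates, cohort)
            matrix, qc = preprocess_plates(plates_f, seed=sim.seed)
            paths = [
                _write_tsv(qc.metabolite.reset_index(), outdir / "qc_report.tsv"),
                _write_tsv(
                    matrix.data.reset_index(names="participant_id"),
                    outdir / "metabolite_matrix.csv",
                    sep=",",
                ),
                _write_json(tally, outdir / "exclusion_tally.json"),
            ]
            _record(manifest, stage, paths)
        elif stage == "associate":
            _require(matrix is not None, stage)
            lin = bonferroni_adjust(
                fit_linear_assoc(matrix, cohort, ModelSpec("bmi", "full")),
                config.m_tests,
                config.alpha,
            )
            logi = bonferroni_adjust(
                fit_logistic_assoc(matrix, cohort, ModelSpec("t2d", "full")),
                config.m_tests,
                config.alpha,
            )
            stair = model_staircase(matrix, cohort, config.alpha, config.m_tests)
            volcano = lin[["metabolite", "beta", "pvalue", "significant"]].copy()
            volcano["neg_log10_p"] = -np.log10(volcano["pvalue"])
            paths = [
                _write_tsv(lin, outdir / "assoc_bmi_full.tsv"),
                _write_tsv(logi, outdir / "assoc_t2d_full.tsv"),
                _write_tsv(stair.reset_index(), outdir / "model_staircase.tsv"),
                _write_tsv(volcano, outdir / "volcano_bmi_full.tsv"),
            ]
            _record(manifest, stage, paths)
        elif stage == "mediate":
            _require(matrix is not None, stage)
            glu = run_mediation_screen(matrix, cohort, "fasting_glucose", config.alpha, config.m_tests)
            hba = run_mediation_screen(matrix, cohort, "hba1c", config.alpha, config.m_tests)
            both = mediation_intersection(glu, hba)
            paths = [
                _write_tsv(glu, outdir / "mediation_glucose.tsv"),
                _write_tsv(hba, outdir / "mediation_hba1c.tsv"),
                _write_json({"significant_in_both": both}, outdir / "mediation_intersection.json"),
            ]
            _record(manifest, stage, paths)
        elif stage == "mr":
            bmi_gwas, met_gwas, truth1 = generate_gwas_summaries(sim)
            sim2 = dataclasses.replace(
                sim, seed=sim.seed + 1, mr_truth=config.mr_truth_secondary
            )
            met_exp_gwas, t2d_gwas, truth2 = generate_gwas_summaries(sim2)
            # the metabolite's own instruments are distinct loci from the
            # BMI instruments; rename to keep SNP ids unique across tables
            met_exp_gwas["SNP"] = met_exp_gwas["SNP"] + "_m"
            t2d_gwas["SNP"] = t2d_gwas["SNP"] + "_m"
            met_table = _stack_gwas(met_gwas, met_exp_gwas)
            results = run_bidirectional_mr(
                bmi_gwas,
                met_table,
                t2d_gwas,
                ld_bmi=identity_ld(bmi_gwas["SNP"]),
                ld_metabolite=identity_ld(met_table["SNP"]),
            )
            table = results_table(results)
            paths = [
                mio.write_gwas(bmi_gwas, outdir / "gwas_bmi.tsv"),
                mio.write_gwas(met_gwas, outdir / "gwas_metabolite_outcome.tsv"),
                mio.write_gwas(met_exp_gwas, outdir / "gwas_metabolite_exposure.tsv"),
                mio.write_gwas(t2d_gwas, outdir / "gwas_t2d.tsv"),
                _write_tsv(table, outdir / "mr_results.tsv"),
                mio.write_truth(truth1, outdir / "mr_truth_direction1.json"),
                mio.write_truth(truth2, outdir / "mr_truth_direction2.json"),
            ]
            _record(manifest, stage, paths)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def _stack_gwas(as_outcome: pd.DataFrame, as_exposure: pd.DataFrame) -> pd.DataFrame:
    """One metabolite GWAS table serving both directions: its rows for the
    BMI instruments (outcome side) plus its own instruments (exposure side)."""
    clash = set(as_exposure["SNP"]) & set(as_outcome["SNP"])
    if clash:
        raise DependencyError(f"duplicate SNP ids across metabolite GWAS sides: {sorted(clash)[:3]}")
    return pd.concat([as_outcome, as_exposure], ignore_index=True)


def _restrict_plates(plates, cohort):
    keep_ids = set(cohort["participant_id"])
    out = plates.copy()
    is_sample = out.data["role"] == "sample"
    drop = is_sample & ~out.data["participant_id"].isin(keep_ids)
    out.data = out.data[~drop]
    out.nondetect = out.nondetect.loc[out.data.index]
    return out


def _require(ok: bool, stage: str) -> None:
    if not ok:
        raise DependencyError(f"stage '{stage}' enabled but its upstream output is missing")


def _write_tsv(df: pd.DataFrame, path: Path, sep: str = "\t") -> Path:
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def _write_json(payload, path: Path) -> Path:
    path.write_text(json.dumps(payload, indent=2))
    return path


def _config_snapshot(config: RunConfig) -> dict:
    snap = dataclasses.asdict(config)
    return snap


# ---------------------------------------------------------------------------
# descriptive summary


def summarize_cohort(cohort: pd.DataFrame, stratifier: str = "obesity") -> dict[str, pd.DataFrame]:
    """Stratified descriptive table: mean (SD) + t-test for continuous
    variables, count (%) + chi-square for categorical ones.

    ``stratifier`` is "obesity" (obese ⇔ BMI ≥ 30) or "t2d". Percentages
    are also reported rounded to one decimal (``pct``), the precision of
    the published-table convention.
    """
    if stratifier == "obesity":
        group = (cohort["bmi"] >= 30).map({False: "non-obese", True: "obese"})
        extra_cat = [("t2d", cohort["t2d"].map({0: "no", 1: "yes"}))]
    elif stratifier == "t2d":
        group = cohort["t2d"].map({0: "T2D-no", 1: "T2D-yes"})
        extra_cat = [("obese", (cohort["bmi"] >= 30).map({False: "no", True: "yes"}))]
    else:
        raise SummaryError(f"unknown stratifier '{stratifier}'")
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise SummaryError("a stratum is empty")

    cont_rows = []
    for var in _CONTINUOUS_VARS:
        if var not in cohort.columns:
            continue
        vals = [cohort.loc[group == g, var].dropna() for g in levels]
        if any(len(v) < 2 for v in vals):
            raise SummaryError(f"empty stratum for {var}")
        t_p = float(stats.ttest_ind(vals[0], vals[1], equal_var=False).pvalue)
        row = {"variable": var, "pvalue": t_p}
        for g, v in zip(levels, vals):
            row[f"{g}_mean"] = float(v.mean())
            row[f"{g}_sd"] = float(v.std(ddof=1))
        cont_rows.append(row)

    cat_rows = []
    cat_vars = [(v, cohort[v]) for v in _CATEGORICAL_VARS if v in cohort.columns] + extra_cat
    for var, series in cat_vars:
        table = pd.crosstab(series, group)
        if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
            raise SummaryError(f"empty stratum for {var}")
        chi2_p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        for level in table.index:
            row = {"variable": var, "level": level, "pvalue": chi2_p}
            for g in levels:
                count = int(table.loc[level, g])
                total = int(table[g].sum())
                row[f"{g}_count"] = count
                row[f"{g}_pct"] = round(100.0 * count / total, 1)
            cat_rows.append(row)

    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
    }
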