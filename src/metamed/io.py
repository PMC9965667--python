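"""Plain-text readers/writers for the pipeline's table dialects.

Cohort tables are CSV with a documented header; plates are one CSV per
plate with a ``role`` column in {zero, reference, sample} and
non-detectable cells encoded as the literal token ``ND``; GWAS summary
statistics use the common seven-column TSV dialect (SNP, effect_allele,
other_allele, eaf, beta, se, pval); LD matrices are TSV with the SNP ids
as both header row and first column; truth records are JSON.
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import RawPlateMatrix, TruthRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_plates",
    "read_plates",
    "write_gwas",
    "read_gwas",
    "write_ld",
    "read_ld",
    "write_truth",
    "read_truth",
]

_ND_TOKEN = "ND"
_FLOAT_FMT = "%.10g"


def write_cohort(cohort: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    public = cohort[[c for c in cohort.columns if not c.startswith("_")]]
    public.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_plates(plates: RawPlateMatrix, outdir: str | os.PathLike) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    met_cols = plates.metabolites
    for plate_id, block in plates.data.groupby("plate", sort=True):
        out = block.copy()
        nd = plates.nondetect.loc[block.index, met_cols].to_numpy()
        vals = out[met_cols].to_numpy(dtype=object)
        vals[nd] = _ND_TOKEN
        out[met_cols] = vals
        path = outdir / f"plate_{int(plate_id):02d}.csv"
        out.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    return written


def read_plates(paths: Iterable[str | os.PathLike]) -> RawPlateMatrix:
    frames = []
    for path in sorted(Path(p) for p in paths):
        frames.append(pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False,
                                  na_values=[""]))
    if not frames:
        raise InputError("no plate files given")
    data = pd.concat(frames, ignore_index=True)
    met_cols = [c for c in data.columns if c.startswith("met_")]
    nd = pd.DataFrame(False, index=data.index, columns=met_cols)
    for col in met_cols:
        mask = data[col].astype(str).str.strip() == _ND_TOKEN
        nd[col] = mask.to_numpy()
        data[col] = pd.to_numeric(data[col].mask(mask), errors="coerce")
    data["participant_id"] = data["participant_id"].fillna("")
    return RawPlateMatrix(data=data, nondetect=nd)


def write_gwas(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_gwas(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld(ld: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    ld.to_csv(path, sep="\t", index=True, index_label="SNP", float_format=_FLOAT_FMT)
    return path


def read_ld(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SNP")


def write_truth(truth: TruthRecord, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_truth(path: str | os.PathLike) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text())
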