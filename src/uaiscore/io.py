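"""Readers and writers for the pipeline's on-disk dialects.

Expression travels as TSV with genes as rows and a header row of sample IDs
(the dominant bulk-transcriptomics layout); clinical, truth and score tables
travel as CSV. Reading validates identifiers, numeric values and survival
fields and reports offending rows by line number.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "CLINICAL_COLUMNS",
]

#: canonical clinical column order
CLINICAL_COLUMNS = [
    "sample_id",
    "arm",
    "dfs_time",
    "dfs_event",
    "os_time",
    "os_event",
    "ctdna_c1d1",
    "ctdna_c3d1",
    "ttmb",
    "pdl1",
]

_ARM_ALIASES = {"io": "IO", "obs": "Obs", "observation": "Obs", "atezo": "IO"}
_BIOMARKER_COLS = ["ctdna_c1d1", "ctdna_c3d1", "ttmb", "pdl1"]
_BIOMARKER_LEVELS = {
    "ctdna_c1d1": {"pos", "neg"},
    "ctdna_c3d1": {"pos", "neg"},
    "ttmb": {"pos", "neg"},
    "pdl1": {"IC23", "IC01"},
}


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    Raises ``ValueError`` on duplicate gene/sample identifiers or
    non-numeric/non-finite values, naming the offending rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [
            f"line {i + 2} (gene {g})"
            for i, g in enumerate(df.index)
            if not pd.to_numeric(df.loc[g], errors="coerce").notna().all()
        ]
        raise ValueError(f"non-numeric expression values in {path}: {bad[:5]}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = values.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValueError(f"non-finite expression values in {path} for genes {bad[:5]}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "gene_id"
    return values


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical CSV.

    Arm labels are case-folded (``obs`` -> ``Obs``); unknown labels, duplicate
    sample ids and non-positive times raise ``ValueError`` with line numbers.
    ``os_time < dfs_time`` rows are accepted with a warning (user data may
    encode endpoints differently; simulated data never trips this).
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} lacks required columns {missing}")
    if df["sample_id"].duplicated().any():
        lines = (df.index[df["sample_id"].duplicated()] + 2).tolist()
        raise ValueError(f"duplicate sample ids in {path} at lines {lines[:5]}")

    arm = df["arm"].astype(str)
    folded = arm.str.lower().map(_ARM_ALIASES)
    unknown = folded.isna()
    if unknown.any():
        lines = (df.index[unknown] + 2).tolist()
        raise ValueError(
            f"unknown arm labels in {path} at lines {lines[:5]}: "
            f"{arm[unknown].unique().tolist()[:5]} (expected IO/Obs)"
        )
    df["arm"] = folded.values

    for col in ("dfs_time", "os_time"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(f"non-positive or non-numeric {col} in {path} at lines {lines[:5]}")
        df[col] = vals
    for col in ("dfs_event", "os_event"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(f"{col} not in {{0,1}} in {path} at lines {lines[:5]}")
        df[col] = vals.astype(int)

    viol = df["os_time"] < df["dfs_time"]
    if viol.any():
        warnings.warn(
            f"{int(viol.sum())} samples in {path} have os_time < dfs_time; "
            "check endpoint definitions",
            UserWarning,
            stacklevel=2,
        )

    for col in _BIOMARKER_COLS:
        if col not in df.columns:
            df[col] = pd.NA
            continue
        vals = df[col].where(df[col].notna() & (df[col].astype(str) != ""), pd.NA)
        known = _BIOMARKER_LEVELS[col] | {"NA"}
        bad = vals.notna() & ~vals.astype(str).isin(known)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(
                f"unknown {col} level in {path} at lines {lines[:5]}: "
                f"{vals[bad].unique().tolist()[:5]}"
            )
        df[col] = vals.replace("NA", pd.NA)

    return df.set_index("sample_id", drop=False)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.reset_index(drop=True)
    cols = [c for c in CLINICAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, na_rep="NA")


def biomarker_indicator(clinical: pd.DataFrame, name: str) -> pd.Series:
    """0/1/NaN coding of a tri-state biomarker column (pos/IC23 = 1)."""
    positive = {"pos", "IC23"}
    col = clinical[name]
    out = pd.Series(np.nan, index=clinical.index, name=name)
    out[col.astype("string").isin(positive).fillna(False)] = 1.0
    negative = {"neg", "IC01"}
    out[col.astype("string").isin(negative).fillna(False)] = 0.0
    return out
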