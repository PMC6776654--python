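"""TSV readers/writers with validation.

Canonical dialect: tab-separated, UTF-8, '.' decimal, 'NA' for missing.
Sample-indexed tables carry their sample identifiers in a first column
named ``sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "read_feature_table",
    "read_metabolite_table",
    "read_pedigree",
    "read_covariates",
    "read_annotation",
    "read_compound_map",
    "write_table",
]

NA_TOKEN = "NA"


def _read_sample_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, sample {row!r}"
            )
        df[col] = vals
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Sample x feature relative abundances; values must lie in [0, 1]."""
    df = _read_sample_table(path, "features")
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        i, j = map(int, np.argwhere(bad & ~np.isnan(vals))[0])
        raise ValueError(
            f"{path}: abundance out of [0, 1] at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}: {vals[i, j]}"
        )
    return df


def read_metabolite_table(path) -> pd.DataFrame:
    """Sample x metabolite intensities; present values must be positive."""
    df = _read_sample_table(path, "metabolites")
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) & ~np.isnan(vals)
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: negative intensity at sample {df.index[i]!r}, "
            f"metabolite {df.columns[j]!r}"
        )
    return df


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    return Pedigree(df)


def read_covariates(path) -> pd.DataFrame:
    """Covariate table: sample_id plus numeric columns (sex, age, optional
    runday and drug flags)."""
    return _read_sample_table(path, "covariates")


def read_annotation(path) -> pd.DataFrame:
    """Metabolite annotation: metabolite_id plus super_pathway and/or
    compound_key columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN],
                     keep_default_na=False)
    if "metabolite_id" not in df.columns:
        raise ValueError(f"{path}: missing 'metabolite_id' column")
    if df["metabolite_id"].duplicated().any():
        dup = df.loc[df["metabolite_id"].duplicated(), "metabolite_id"].iloc[0]
        raise ValueError(f"{path}: duplicate metabolite_id {dup!r}")
    return df.set_index("metabolite_id")


def read_compound_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN],
                     keep_default_na=False)
    for col in ("compound_key", "pathway_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col!r} column")
    return df


def write_table(df: pd.DataFrame, path, index_label: str | None = "sample_id") -> None:
    """Write a table in the canonical TSV dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if index_label is None:
        df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=False)
    else:
        df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=index_label)
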