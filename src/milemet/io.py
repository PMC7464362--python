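"""Readers and writers for the pipeline's CSV interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ANTHRO_COLUMNS = ["subject_id", "sex", "age_months", "bmi"]


def read_anthropometry(path) -> pd.DataFrame:
    """Long-format anthropometry: subject_id, sex, age_months, bmi.

    Validates sex levels, age/BMI ranges and (subject, age) uniqueness.
    """
    df = pd.read_csv(path)
    missing = set(ANTHRO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"anthropometry table missing columns {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex levels {sorted(bad_sex)}")
    if ((df["age_months"] < 0) | (df["age_months"] > 240)).any():
        raise ValueError("age_months outside [0, 240]")
    if ((df["bmi"] <= 5) | (df["bmi"] >= 60)).any():
        raise ValueError("bmi outside (5, 60)")
    if df.duplicated(["subject_id", "age_months"]).any():
        raise ValueError("duplicate (subject_id, age_months) rows")
    return df


def read_metabolite_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("metabolite matrix needs a subject_id column")
    df = df.set_index("subject_id")
    if (df.fillna(0) < 0).any().any():
        raise ValueError("negative abundances in metabolite matrix")
    return df


def read_metabolite_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"metabolite_id", "endogenous"}
    if required - set(meta.columns):
        raise ValueError("metabolite metadata needs metabolite_id and "
                         "endogenous columns")
    return meta


def read_reference_tables(path) -> pd.DataFrame:
    ref = pd.read_csv(path)
    required = {"component", "sex", "age_bin_lo", "age_bin_hi", "mean", "sd"}
    if required - set(ref.columns):
        raise ValueError(f"reference table missing columns "
                         f"{sorted(required - set(ref.columns))}")
    if (ref["sd"] <= 0).any():
        raise ValueError("reference table contains non-positive SDs")
    return ref


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path, overwrite=True, sep=",") -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, sep=sep)
    return path
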