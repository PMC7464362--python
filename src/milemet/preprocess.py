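"""Metabolite preprocessing: endogenous filter, half-minimum imputation,
log10 transform, Pareto scaling.

The pipeline order is fixed (filter -> impute -> log -> Pareto) and a
processed matrix refuses a second pass.  Pareto scaling mean-centres each
logged compound and divides by the square root of its sample standard
deviation (n-1 denominator), damping the influence of high-variance
compounds less aggressively than unit-variance scaling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROCESSED_FLAG = "milemet_processed"


def filter_endogenous(matrix: pd.DataFrame, meta: pd.DataFrame
                      ) -> pd.DataFrame:
    """Retain only metabolite columns flagged endogenous in the metadata."""
    if "endogenous" not in meta.columns or "metabolite_id" not in meta.columns:
        raise ValueError("metadata must provide metabolite_id and endogenous")
    flags = meta.set_index("metabolite_id")["endogenous"].astype(bool)
    missing = [c for c in matrix.columns if c not in flags.index]
    if missing:
        raise ValueError(f"no endogenous flag for metabolites {missing[:5]}")
    keep = [c for c in matrix.columns if flags[c]]
    if not keep:
        raise ValueError("no endogenous metabolites; matrix unusable")
    logger.info("endogenous filter: retained %d of %d metabolites",
                len(keep), matrix.shape[1])
    return matrix[keep]


def impute_half_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values with half the per-metabolite minimum detected
    value (limit-of-detection interpretation)."""
    fully_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError("metabolites with no detected values: "
                         f"{list(fully_missing[:5])}")
    mins = matrix.min(axis=0, skipna=True)
    n_imputed = int(matrix.isna().to_numpy().sum())
    out = matrix.fillna(0.5 * mins)
    logger.info("half-minimum imputation: %d values imputed", n_imputed)
    return out


def log_pareto_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10 then Pareto scale each compound: (x - mean) / sqrt(sd)."""
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("non-positive abundances; impute before transforming")
    logged = np.log10(matrix)
    sd = logged.std(axis=0, ddof=1)
    zero_var = sd.index[~(sd > 0)]
    if len(zero_var):
        raise ValueError(f"zero-variance metabolites after log transform: "
                         f"{list(zero_var[:5])}")
    return (logged - logged.mean(axis=0)) / np.sqrt(sd)


class MetabolitePreprocessor:
    """End-to-end preprocessing transformer (scikit-learn style).

    ``fit_transform(matrix, meta)`` applies, in order: endogenous filter,
    half-minimum imputation, log10, Pareto scaling, and records a
    preprocessing report (counts, imputation tallies).  Transforming an
    already-processed matrix raises.
    """

    def __init__(self, require_endogenous: bool = True):
        self.require_endogenous = require_endogenous

    def get_params(self, deep=True):
        return {"require_endogenous": self.require_endogenous}

    def set_params(self, **params):
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit_transform(self, matrix: pd.DataFrame,
                      meta: pd.DataFrame | None = None) -> pd.DataFrame:
        if matrix.attrs.get(PROCESSED_FLAG):
            raise ValueError("matrix is already preprocessed; the pipeline "
                             "is not idempotent and refuses a second pass")
        n_total = matrix.shape[1]
        if self.require_endogenous:
            if meta is None:
                raise ValueError("metadata required for the endogenous filter")
            matrix = filter_endogenous(matrix, meta)
        n_missing = int(matrix.isna().to_numpy().sum())
        imputed = impute_half_min(matrix)
        out = log_pareto_transform(imputed)
        out.attrs[PROCESSED_FLAG] = True
        self.report_ = {
            "n_metabolites_input": int(n_total),
            "n_metabolites_endogenous": int(matrix.shape[1]),
            "n_values_imputed": n_missing,
            "n_samples": int(matrix.shape[0]),
        }
        return out
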