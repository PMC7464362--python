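"""Metabolic syndrome (MetS) z-score from externally standardized components.

The composite is the mean of five component z-scores — waist
circumference, average systolic blood pressure, HDL cholesterol
(reversed), triglycerides, and HOMA-IR — each standardized against an
external sex/age(/height)-stratified mean/SD reference table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPONENTS = ("waist", "sbp", "hdl", "triglycerides", "homa_ir")


def homa_ir(glucose_mgdl, insulin_uiu_ml):
    """HOMA-IR = glucose [mg/dL] x insulin [uIU/mL] / 405."""
    glucose = np.asarray(glucose_mgdl, dtype=float)
    insulin = np.asarray(insulin_uiu_ml, dtype=float)
    if (glucose <= 0).any() or (insulin <= 0).any():
        raise ValueError("glucose and insulin must be positive")
    return glucose * insulin / 405.0


def average_sbp(readings) -> float | np.ndarray:
    """Arithmetic mean of the systolic readings (nominally five)."""
    readings = np.atleast_2d(np.asarray(readings, dtype=float))
    n = readings.shape[1]
    if n == 0:
        raise ValueError("no SBP readings")
    if n < 5:
        logger.warning("averaging %d SBP readings instead of 5", n)
    out = readings.mean(axis=1)
    return out if out.size > 1 else float(out[0])


class ExternalStandardizer:
    """Resolve (component, sex, age[, height]) to a reference mean/SD and
    return z = (value - mean) / sd.  Age and height bins are closed-open
    [lo, hi)."""

    def __init__(self, reference: pd.DataFrame):
        required = {"component", "sex", "age_bin_lo", "age_bin_hi",
                    "mean", "sd"}
        if required - set(reference.columns):
            raise ValueError("reference table missing columns "
                             f"{sorted(required - set(reference.columns))}")
        if (reference["sd"] <= 0).any():
            raise ValueError("reference SDs must be positive")
        self.reference = reference.copy()

    def standardize(self, value, component: str, sex: str, age_years: float,
                    height_cm: float | None = None) -> float:
        ref = self.reference
        rows = ref[(ref["component"] == component) & (ref["sex"] == sex)
                   & (ref["age_bin_lo"] <= age_years)
                   & (age_years < ref["age_bin_hi"])]
        uses_height = ("height_bin_lo" in rows.columns
                       and rows["height_bin_lo"].notna().any())
        if uses_height:
            if height_cm is None:
                raise KeyError(f"component {component!r} reference is "
                               "height-stratified but no height given")
            rows = rows[(rows["height_bin_lo"] <= height_cm)
                        & (height_cm < rows["height_bin_hi"])]
        if len(rows) == 0:
            raise KeyError(f"no reference stratum for component="
                           f"{component!r}, sex={sex!r}, age={age_years}"
                           + (f", height={height_cm}" if uses_height else ""))
        row = rows.iloc[0]
        return (value - row["mean"]) / row["sd"]

    def standardize_series(self, values: np.ndarray, component: str,
                           sex: np.ndarray, age_years: np.ndarray,
                           height_cm: np.ndarray | None = None) -> np.ndarray:
        """Vectorized standardization of one component over many subjects."""
        values = np.asarray(values, dtype=float)
        sex = np.asarray(sex)
        age_years = np.asarray(age_years, dtype=float)
        ref = self.reference[self.reference["component"] == component]
        uses_height = ("height_bin_lo" in ref.columns
                       and ref["height_bin_lo"].notna().any())
        if uses_height and height_cm is None:
            raise KeyError(f"component {component!r} reference is "
                           "height-stratified but no height given")
        out = np.full(values.shape, np.nan)
        for _, row in ref.iterrows():
            mask = ((sex == row["sex"]) & (row["age_bin_lo"] <= age_years)
                    & (age_years < row["age_bin_hi"]))
            if uses_height:
                mask &= ((row["height_bin_lo"] <= height_cm)
                         & (height_cm < row["height_bin_hi"]))
            out[mask] = (values[mask] - row["mean"]) / row["sd"]
        if np.isnan(out).any():
            i = int(np.flatnonzero(np.isnan(out))[0])
            raise KeyError(f"no reference stratum for component="
                           f"{component!r}, sex={sex[i]!r}, "
                           f"age={age_years[i]}")
        return out


def composite_mets_z(z_waist, z_sbp, z_hdl, z_triglycerides, z_homa_ir):
    """Mean of the five component z-scores with HDL entering negated."""
    parts = [z_waist, z_sbp, -1.0 * np.asarray(z_hdl, dtype=float),
             z_triglycerides, z_homa_ir]
    arr = np.column_stack([np.atleast_1d(np.asarray(p, dtype=float))
                           for p in parts])
    if np.isnan(arr).any():
        raise ValueError("missing component z-score; subject must be "
                         "excluded upstream")
    out = arr.mean(axis=1)
    return out if out.size > 1 else float(out[0])


def compute_mets_scores(components: pd.DataFrame, reference: pd.DataFrame
                        ) -> pd.DataFrame:
    """Per-subject component z-scores and the composite MetS z-score.

    ``components`` needs subject_id, sex, age_years, waist_cm, sbp_1..sbp_5
    (at least one reading), hdl_mgdl, triglycerides_mgdl, glucose_mgdl,
    insulin_uiu_ml, and height_cm when the SBP reference is
    height-stratified.
    """
    std = ExternalStandardizer(reference)
    sbp_cols = [c for c in components.columns if c.startswith("sbp_")]
    if not sbp_cols:
        raise ValueError("no SBP reading columns (sbp_1..sbp_5)")
    sbp_vals = components[sbp_cols].to_numpy(dtype=float)
    n_readings = (~np.isnan(sbp_vals)).sum(axis=1)
    if (n_readings == 0).any():
        raise ValueError("subjects with no SBP readings")
    if (n_readings < 5).any():
        logger.warning("%d subjects with fewer than 5 SBP readings",
                       int((n_readings < 5).sum()))
    sbp = np.nanmean(sbp_vals, axis=1)
    homa = homa_ir(components["glucose_mgdl"], components["insulin_uiu_ml"])
    sex = components["sex"].to_numpy()
    age = components["age_years"].to_numpy(dtype=float)
    height = (components["height_cm"].to_numpy(dtype=float)
              if "height_cm" in components.columns else None)
    out = pd.DataFrame({
        "subject_id": components["subject_id"].to_numpy(),
        "sex": sex,
        "z_waist": std.standardize_series(components["waist_cm"], "waist",
                                          sex, age),
        "z_sbp": std.standardize_series(sbp, "sbp", sex, age, height),
        "z_hdl": std.standardize_series(components["hdl_mgdl"], "hdl",
                                        sex, age),
        "z_triglycerides": std.standardize_series(
            components["triglycerides_mgdl"], "triglycerides", sex, age),
        "z_homa_ir": std.standardize_series(homa, "homa_ir", sex, age),
    })
    out["mets_z"] = composite_mets_z(out["z_waist"], out["z_sbp"],
                                     out["z_hdl"], out["z_triglycerides"],
                                     out["z_homa_ir"])
    return out
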