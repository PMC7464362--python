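"""Sex-stratified three-step meet-in-the-middle association screen.

Step 1 relates the four BMI-milestone exposures (per within-sex SD) to the
MetS z-score; milestones significant at alpha are carried forward.
Step 2 regresses each module eigengene on each carried milestone
(race/ethnicity- and age-adjusted) and applies Benjamini-Hochberg FDR
within each sex's family of tests; FDR-significant (milestone, module)
pairs are carried forward.
Step 3 relates carried eigengenes to the MetS z-score under nested
covariate tiers, with an uncorrected per-component follow-up for
eigengenes significant under Model 1.  A mutual-adjustment sensitivity
analysis re-fits step-2 models adding the contemporaneous milestone
(age adjusted for magnitude and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ScreenConfig

MODEL1 = ("age_years", "race_ethnicity")
MODEL2 = MODEL1 + ("puberty_score",)
MODEL3 = MODEL2 + ("maternal_college", "prepreg_bmi", "smoking")
TIERS = {"unadjusted": (), "M1": MODEL1, "M2": MODEL2, "M3": MODEL3}

MILESTONE_SIBLING = {"age_peak": "bmi_peak", "bmi_peak": "age_peak",
                     "age_rebound": "bmi_rebound",
                     "bmi_rebound": "age_rebound"}

COMPONENT_Z = ("z_waist", "z_homa_ir", "z_hdl", "z_triglycerides", "z_sbp")

_CATEGORICAL = ("race_ethnicity", "smoking")


@dataclass
class AssociationResult:
    """One exposure -> outcome linear model summary."""

    stratum: str
    exposure: str
    outcome: str
    tier: str
    beta: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int
    nominal_flag: bool = False
    fdr_flag: bool = False

    def to_dict(self):
        return asdict(self)


RESULT_COLUMNS = ["stratum", "exposure", "outcome", "tier", "beta", "ci_lo",
                  "ci_hi", "p", "n", "nominal_flag", "fdr_flag"]


def _results_table(results) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.DataFrame([r.to_dict() for r in results])[RESULT_COLUMNS]


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    thresholds = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresholds
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below).max())
        flags[order[: k + 1]] = True
    return flags


def _expand_terms(data: pd.DataFrame, terms) -> pd.DataFrame:
    pieces = []
    for term in terms:
        col = data[term]
        if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
                or term in _CATEGORICAL):
            dummies = pd.get_dummies(col.astype(str), prefix=term,
                                     drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).to_frame(term))
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=data.index)


def _aliased_columns(X: np.ndarray, names) -> list[str]:
    aliased, kept = [], []
    for j, name in enumerate(names):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            aliased.append(name)
        else:
            kept.append(j)
    return aliased


def fit_linear_association(data: pd.DataFrame, outcome: str, exposure: str,
                           covariates=(), stratum: str = "all",
                           tier: str = "") -> AssociationResult:
    """Complete-case OLS of ``outcome`` on ``exposure`` + covariates.

    Categorical covariates are expanded to indicator contrasts; the 95% CI
    comes from the t distribution.  Rank-deficient designs raise with the
    aliased terms named.
    """
    if exposure in covariates:
        raise ValueError("exposure cannot also be a covariate")
    cols = [outcome, exposure, *covariates]
    rows = data[cols].dropna()
    design = _expand_terms(rows, [exposure, *covariates])
    design.insert(0, "const", 1.0)
    y = rows[outcome].astype(float)
    if y.nunique() <= 1:
        raise ValueError(f"outcome {outcome!r} is constant")
    if len(rows) < design.shape[1] + 2:
        raise ValueError(f"too few complete cases (n={len(rows)}) for "
                         f"{design.shape[1]} model terms")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design; aliased terms: "
                         f"{_aliased_columns(X, design.columns.tolist())}")
    res = sm.OLS(y.to_numpy(), X).fit()
    idx = design.columns.get_loc(exposure)
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        stratum=stratum, exposure=exposure, outcome=outcome, tier=tier,
        beta=float(res.params[idx]), ci_lo=float(ci[idx, 0]),
        ci_hi=float(ci[idx, 1]), p=float(res.pvalues[idx]), n=int(res.nobs))


def _assemble(milestones: pd.DataFrame,
              eigengenes: dict[str, pd.DataFrame] | None,
              mets_z: pd.DataFrame | None,
              covariates: pd.DataFrame) -> pd.DataFrame:
    """Merge analysis tables into one frame keyed by subject_id."""
    df = milestones.merge(covariates, on=["subject_id", "sex"], how="left")
    if mets_z is not None:
        df = df.merge(mets_z[["subject_id", "mets_z", *COMPONENT_Z]],
                      on="subject_id", how="left")
    if eigengenes is not None:
        blocks = []
        for stratum, eig in eigengenes.items():
            block = eig.copy()
            block.index.name = "subject_id"
            blocks.append(block.reset_index())
        df = df.merge(pd.concat(blocks, ignore_index=True),
                      on="subject_id", how="left")
    return df


def run_step1(milestones_scaled: pd.DataFrame, mets_z: pd.DataFrame,
              covariates: pd.DataFrame,
              config: ScreenConfig | None = None
              ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Milestones (per SD) vs MetS z-score, unadjusted and M1-adjusted.

    Returns the result table and, per sex, the milestones significant at
    alpha in the adjusted model (carried to step 2).
    """
    config = config or ScreenConfig()
    df = _assemble(milestones_scaled, None, mets_z, covariates)
    results, carried = [], {}
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex]
        carried[sex] = []
        for exposure in ("age_peak", "bmi_peak", "age_rebound",
                         "bmi_rebound"):
            for tier, covs in (("unadjusted", ()), ("M1", MODEL1)):
                res = fit_linear_association(sub, "mets_z", exposure, covs,
                                             stratum=sex, tier=tier)
                res.nominal_flag = res.p < config.alpha
                results.append(res)
                if tier == "M1" and res.nominal_flag:
                    carried[sex].append(exposure)
    return _results_table(results), carried


def run_step2(carried: dict[str, list[str]],
              milestones_scaled: pd.DataFrame,
              eigengenes: dict[str, pd.DataFrame],
              covariates: pd.DataFrame,
              config: ScreenConfig | None = None
              ) -> tuple[pd.DataFrame, dict[str, list[tuple[str, str]]]]:
    """Carried milestones vs module eigengenes (ME as outcome), M1-adjusted,
    with BH-FDR within each sex's family of tests."""
    config = config or ScreenConfig()
    df = _assemble(milestones_scaled, eigengenes, None, covariates)
    me_cols = sorted({c for eig in eigengenes.values() for c in eig.columns},
                     key=lambda c: int(c[2:]))
    results, carried_pairs = [], {}
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex]
        sex_results = []
        for exposure in carried.get(sex, []):
            for me in me_cols:
                res = fit_linear_association(sub, me, exposure, MODEL1,
                                             stratum=sex, tier="M1")
                res.nominal_flag = res.p < config.alpha
                sex_results.append(res)
        if config.fdr_family == "joint":
            families = [sex_results]
        else:
            families = [[r for r in sex_results if r.exposure == e]
                        for e in carried.get(sex, [])]
        for family in families:
            if not family:
                continue
            flags = bh_fdr([r.p for r in family], config.q_fdr)
            for r, f in zip(family, flags):
                r.fdr_flag = bool(f)
        carried_pairs[sex] = [(r.exposure, r.outcome) for r in sex_results
                              if r.fdr_flag]
        results.extend(sex_results)
    return _results_table(results), carried_pairs


def run_step3(carried_pairs: dict[str, list[tuple[str, str]]],
              eigengenes: dict[str, pd.DataFrame], mets_z: pd.DataFrame,
              covariates: pd.DataFrame, milestones: pd.DataFrame,
              config: ScreenConfig | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carried eigengenes vs MetS z-score under nested covariate tiers,
    plus the uncorrected per-component follow-up for Model-1-significant
    eigengenes."""
    config = config or ScreenConfig()
    df = _assemble(milestones, eigengenes, mets_z, covariates)
    results, component_results = [], []
    for sex in ("male", "female"):
        mes = sorted({me for _, me in carried_pairs.get(sex, [])},
                     key=lambda c: int(c[2:]))
        sub = df[df["sex"] == sex]
        for me in mes:
            m1_significant = False
            for tier, covs in TIERS.items():
                res = fit_linear_association(sub, "mets_z", me, covs,
                                             stratum=sex, tier=tier)
                res.nominal_flag = res.p < config.alpha
                results.append(res)
                if tier == "M1":
                    m1_significant = res.nominal_flag
            if m1_significant:
                for comp in COMPONENT_Z:
                    res = fit_linear_association(sub, comp, me, MODEL1,
                                                 stratum=sex, tier="M1")
                    res.nominal_flag = res.p < config.alpha
                    component_results.append(res)
    return _results_table(results), _results_table(component_results)


def sensitivity_mutual_adjustment(step2_table: pd.DataFrame,
                                  milestones_scaled: pd.DataFrame,
                                  eigengenes: dict[str, pd.DataFrame],
                                  covariates: pd.DataFrame,
                                  config: ScreenConfig | None = None
                                  ) -> pd.DataFrame:
    """Refit step-2 models adding the contemporaneous milestone (age
    adjusted for magnitude at the same milestone, and vice versa); report
    the original and adjusted betas side by side with the percent change."""
    config = config or ScreenConfig()
    df = _assemble(milestones_scaled, eigengenes, None, covariates)
    rows = []
    for _, rec in step2_table.iterrows():
        sibling = MILESTONE_SIBLING[rec["exposure"]]
        sub = df[df["sex"] == rec["stratum"]]
        pair = sub[[rec["exposure"], sibling]].dropna()
        corr = pair.corr().iloc[0, 1]
        if abs(corr) > 0.99:
            raise ValueError(
                f"age and magnitude of the same milestone are collinear "
                f"(|r|={abs(corr):.3f}) for {rec['exposure']}")
        adj = fit_linear_association(sub, rec["outcome"], rec["exposure"],
                                     (*MODEL1, sibling),
                                     stratum=rec["stratum"],
                                     tier="M1+sibling")
        base = rec["beta"]
        rows.append({
            "stratum": rec["stratum"], "exposure": rec["exposure"],
            "outcome": rec["outcome"], "sibling": sibling,
            "beta_unadjusted_for_sibling": base,
            "ci_lo_unadjusted": rec["ci_lo"],
            "ci_hi_unadjusted": rec["ci_hi"],
            "beta_adjusted": adj.beta, "ci_lo_adjusted": adj.ci_lo,
            "ci_hi_adjusted": adj.ci_hi, "p_adjusted": adj.p,
            "pct_change": (100.0 * (adj.beta - base) / base
                           if base != 0 else np.nan),
        })
    return pd.DataFrame(rows)


def run_screen(milestones_scaled: pd.DataFrame,
               eigengenes: dict[str, pd.DataFrame], mets_z: pd.DataFrame,
               covariates: pd.DataFrame,
               config: ScreenConfig | None = None) -> dict[str, pd.DataFrame]:
    """Full three-step screen plus sensitivity analysis."""
    config = config or ScreenConfig()
    config.validate()
    step1, carried = run_step1(milestones_scaled, mets_z, covariates, config)
    step2, carried_pairs = run_step2(carried, milestones_scaled, eigengenes,
                                     covariates, config)
    step3, components = run_step3(carried_pairs, eigengenes, mets_z,
                                  covariates, milestones_scaled, config)
    sensitivity = (sensitivity_mutual_adjustment(step2, milestones_scaled,
                                                 eigengenes, covariates,
                                                 config)
                   if len(step2) else pd.DataFrame())
    return {"step1": step1, "step2": step2, "step3": step3,
            "components": components, "sensitivity": sensitivity,
            "carried_milestones": carried, "carried_pairs": carried_pairs}
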