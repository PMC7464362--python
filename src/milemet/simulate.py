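"""Synthetic cohort generator with exact ground truth.

Generates (a) longitudinal BMI trajectories whose infancy peak and
childhood rebound are planted analytically, (b) a block-correlated
log-normal metabolome with limit-of-detection censoring, and (c) MetS
components linearly driven by planted module factors and milestones,
together with external standardization reference tables.

The latent BMI curve of each subject is the quartic b(t) whose derivative
is b'(t) = k (t - t_p)(t - t_r)(t + c) with k > 0, c > 0, so the curve has
exactly one interior maximum at t_p (the infancy peak) and one interior
minimum at t_r (the rebound); k and the integration constant are solved so
that b(t_p) = B_p and b(t_p) - b(t_r) equals the drawn peak-to-rebound
drop.  Ground-truth milestones are therefore exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (COMPONENT_NAMES, MILESTONE_NAMES, Effect,
                     SimulationConfig, config_to_dict)

SUPER_PATHWAYS = ("Lipid", "Amino Acid", "Nucleotide", "Carbohydrate",
                  "Cofactors and Vitamins", "Peptide", "Energy",
                  "Xenobiotics")

_MAX_REDRAWS = 100


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    milestones: pd.DataFrame        # subject_id, sex, age_peak, bmi_peak, ...
    module_labels: pd.Series | None = None   # metabolite_id -> module int
    factors: pd.DataFrame | None = None      # subject x module factor scores
    effects: list[dict] | None = None        # configured + realized betas

    def to_dict(self) -> dict:
        out = {"milestones": self.milestones.to_dict(orient="records")}
        if self.module_labels is not None:
            out["module_labels"] = {str(k): int(v)
                                    for k, v in self.module_labels.items()}
        if self.effects is not None:
            out["effects"] = self.effects
        return out


@dataclass
class SyntheticDataset:
    """Bundle of all tables for one simulated cohort."""

    anthropometry: pd.DataFrame
    metabolites: pd.DataFrame
    metabolite_meta: pd.DataFrame
    mets_components: pd.DataFrame
    reference_tables: pd.DataFrame
    covariates: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig


def _truncated_normal(rng, mean, sd, bounds=None, size=None):
    if sd == 0:
        return np.full(size if size is not None else 1, mean)
    out = rng.normal(mean, sd, size=size)
    if bounds is not None:
        lo, hi = bounds
        for _ in range(_MAX_REDRAWS):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                break
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:
            raise RuntimeError("could not draw values inside bounds "
                               f"[{lo}, {hi}] after {_MAX_REDRAWS} redraws")
    return out


def quartic_antiderivative(t, t_p, t_r, c):
    """Antiderivative B(t) of (t - t_p)(t - t_r)(t + c), up to a constant."""
    t = np.asarray(t, dtype=float)
    a3 = (c - t_p - t_r) / 3.0
    a2 = (t_p * t_r - c * (t_p + t_r)) / 2.0
    a1 = c * t_p * t_r
    return 0.25 * t ** 4 + a3 * t ** 3 + a2 * t ** 2 + a1 * t


def latent_curve(t, t_p, B_p, t_r, drop, c):
    """Latent BMI at ages t for one subject's planted milestones."""
    denom = quartic_antiderivative(t_p, t_p, t_r, c) - \
        quartic_antiderivative(t_r, t_p, t_r, c)
    if denom <= 0:
        raise ValueError("degenerate milestone configuration (t_p >= t_r?)")
    k = drop / denom
    return B_p + k * (quartic_antiderivative(t, t_p, t_r, c)
                      - quartic_antiderivative(t_p, t_p, t_r, c))


def latent_curve_derivative(t, t_p, B_p, t_r, drop, c):
    t = np.asarray(t, dtype=float)
    denom = quartic_antiderivative(t_p, t_p, t_r, c) - \
        quartic_antiderivative(t_r, t_p, t_r, c)
    k = drop / denom
    return k * (t - t_p) * (t - t_r) * (t + c)


def simulate_trajectories(config: SimulationConfig, rng=None
                          ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-subject milestones and observe noisy BMI on the schedule.

    Returns a long-format anthropometry table (subject_id, sex, age_months,
    bmi) and the exact ground-truth milestones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = 2 * config.n_per_sex
    sexes = np.array(["male"] * config.n_per_sex
                     + ["female"] * config.n_per_sex)
    subject_ids = np.array([f"S{i + 1:04d}" for i in range(n)])

    t_p = _truncated_normal(rng, config.peak_age_mean, config.peak_age_sd,
                            config.peak_age_bounds, n)
    t_r = _truncated_normal(rng, config.rebound_age_mean,
                            config.rebound_age_sd,
                            config.rebound_age_bounds, n)
    B_p = _truncated_normal(rng, config.peak_magnitude_mean,
                            config.peak_magnitude_sd, (12.0, 26.0), n)
    drop = _truncated_normal(rng, config.drop_mean, config.drop_sd,
                             config.drop_bounds, n)
    for _ in range(_MAX_REDRAWS):
        bad = t_r <= t_p + 10.0  # milestones must be well separated
        if not bad.any():
            break
        t_p[bad] = _truncated_normal(rng, config.peak_age_mean,
                                     config.peak_age_sd,
                                     config.peak_age_bounds, int(bad.sum()))
        t_r[bad] = _truncated_normal(rng, config.rebound_age_mean,
                                     config.rebound_age_sd,
                                     config.rebound_age_bounds,
                                     int(bad.sum()))
    else:
        raise RuntimeError("could not draw t_p < t_r for all subjects")

    ages = np.asarray(config.measurement_ages, dtype=float)
    rows = []
    B_r = np.empty(n)
    for i in range(n):
        latent = latent_curve(ages, t_p[i], B_p[i], t_r[i], drop[i],
                              config.curve_c)
        noise = rng.normal(0.0, config.bmi_noise_sd, size=ages.size) \
            if config.bmi_noise_sd > 0 else 0.0
        bmi = latent + noise
        B_r[i] = B_p[i] - drop[i]
        rows.append(pd.DataFrame({
            "subject_id": subject_ids[i],
            "sex": sexes[i],
            "age_months": ages,
            "bmi": bmi,
        }))
    anthro = pd.concat(rows, ignore_index=True)

    milestones = pd.DataFrame({
        "subject_id": subject_ids,
        "sex": sexes,
        "age_peak": t_p,
        "bmi_peak": B_p,
        "age_rebound": t_r,
        "bmi_rebound": B_r,
    })
    return anthro, GroundTruth(milestones=milestones)


def _standardized_exposure(truth_milestones: pd.DataFrame, name: str,
                           stratum: str) -> pd.Series:
    """Exposure z-scored within its stratum; zero outside the stratum."""
    z = pd.Series(0.0, index=truth_milestones.index)
    if stratum == "both":
        mask = pd.Series(True, index=truth_milestones.index)
    else:
        mask = truth_milestones["sex"] == stratum
    vals = truth_milestones.loc[mask, name]
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError(f"exposure {name!r} has zero SD in stratum {stratum!r}")
    z[mask] = (vals - vals.mean()) / sd
    return z


def build_module_factors(config: SimulationConfig, truth: GroundTruth,
                         rng) -> tuple[pd.DataFrame, list[dict]]:
    """Latent module factors, unit variance per stratum, with planted
    milestone effects folded in.

    For a module receiving effects with coefficients beta_e in a stratum,
    f = (sum_e beta_e z_e + eps) / sqrt(1 + sum beta_e^2), so Var(f) = 1 and
    the realized regression slope of f on z_e is beta_e / sqrt(1 + sum b^2).
    """
    mil = truth.milestones
    n = len(mil)
    eps = rng.standard_normal((n, config.n_modules))
    factors = eps.copy()
    realized: list[dict] = []
    for m in range(1, config.n_modules + 1):
        target = f"module_{m}"
        for stratum in ("male", "female"):
            effs = [e for e in config.effect_map
                    if e.target == target and e.applies_to(stratum)
                    and e.exposure in MILESTONE_NAMES]
            if not effs:
                continue
            mask = (mil["sex"] == stratum).to_numpy()
            total = np.zeros(mask.sum())
            ssq = 0.0
            for e in effs:
                z = _standardized_exposure(mil, e.exposure, stratum)
                total += e.beta * z.to_numpy()[mask]
                ssq += e.beta ** 2
            norm = np.sqrt(1.0 + ssq)
            factors[mask, m - 1] = (total + eps[mask, m - 1]) / norm
            for e in effs:
                realized.append({**dataclasses.asdict(e),
                                 "realized_beta": e.beta / norm})
    # component-targeted effects are realized as configured
    for e in config.effect_map:
        if not e.target.startswith("module_"):
            realized.append({**dataclasses.asdict(e),
                             "realized_beta": e.beta})
    cols = [f"module_{m}" for m in range(1, config.n_modules + 1)]
    fdf = pd.DataFrame(factors, columns=cols,
                       index=mil["subject_id"].to_numpy())
    fdf.index.name = "subject_id"
    return fdf, realized


def simulate_metabolome(config: SimulationConfig, truth: GroundTruth,
                        rng) -> tuple[pd.DataFrame, pd.DataFrame,
                                      pd.DataFrame]:
    """Block-correlated log-normal metabolome with LOD censoring.

    Member metabolite log-abundance = loading * f_m + sqrt(1-loading^2) * e;
    background metabolites are independent noise.  Raw abundances are
    10**(location + 0.3 * log-abundance); per-metabolite values below the
    ``lod_censor_fraction`` quantile are set missing (left-censoring at a
    limit of detection).

    Returns (raw abundance matrix with NaN for censored values, metabolite
    metadata, subject x module factor table).
    """
    total_members = int(sum(config.module_sizes))
    if config.n_metabolites < total_members:
        raise ValueError("module_sizes sum exceeds total metabolite count")
    factors, realized = build_module_factors(config, truth, rng)
    truth.factors = factors
    truth.effects = realized

    n = len(factors)
    lam = config.intra_module_loading
    cols, labels = [], []
    log_ab = np.empty((n, config.n_metabolites))
    j = 0
    for m, size in enumerate(config.module_sizes, start=1):
        f = factors[f"module_{m}"].to_numpy()
        for _ in range(int(size)):
            e = rng.standard_normal(n)
            log_ab[:, j] = lam * f + np.sqrt(1.0 - lam ** 2) * e
            labels.append(m)
            j += 1
    for _ in range(config.n_background_metabolites):
        log_ab[:, j] = rng.standard_normal(n)
        labels.append(0)
        j += 1

    met_ids = [f"M{k + 1:04d}" for k in range(config.n_metabolites)]
    location = rng.uniform(2.5, 5.5, size=config.n_metabolites)
    raw = 10.0 ** (location[None, :] + 0.3 * log_ab)

    if config.lod_censor_fraction > 0:
        cutoffs = np.quantile(raw, config.lod_censor_fraction, axis=0)
        raw = np.where(raw < cutoffs[None, :], np.nan, raw)

    matrix = pd.DataFrame(raw, index=factors.index, columns=met_ids)
    matrix.index.name = "subject_id"

    labels = np.asarray(labels)
    endogenous = np.ones(config.n_metabolites, dtype=bool)
    background_idx = np.flatnonzero(labels == 0)
    n_nonendo = int(round(config.nonendogenous_fraction
                          * config.n_metabolites))
    n_nonendo = min(n_nonendo, background_idx.size)
    if n_nonendo > 0:
        chosen = rng.choice(background_idx, size=n_nonendo, replace=False)
        endogenous[chosen] = False

    pathway = [SUPER_PATHWAYS[(lbl - 1) % len(SUPER_PATHWAYS)] if lbl > 0
               else SUPER_PATHWAYS[int(rng.integers(len(SUPER_PATHWAYS)))]
               for lbl in labels]
    meta = pd.DataFrame({
        "metabolite_id": met_ids,
        "name": [f"compound-{mid[1:]}" for mid in met_ids],
        "super_pathway": pathway,
        "sub_pathway": [f"{p} cluster {lbl}" if lbl > 0 else f"{p} (misc)"
                        for p, lbl in zip(pathway, labels)],
        "endogenous": endogenous,
    })
    truth.module_labels = pd.Series(labels, index=met_ids,
                                    name="module").rename_axis("metabolite_id")
    return matrix, meta, factors


# ---------------------------------------------------------------------------
# MetS components, covariates and reference tables
# ---------------------------------------------------------------------------

#: 1-year age bins through 14, then one wider adolescent tail bin [14, 16)
#: (the cohort age distribution is centred at ~12.9 y and thins out fast).
AGE_BIN_EDGES = np.array([11.0, 12.0, 13.0, 14.0, 16.0])
SBP_HEIGHT_BIN_EDGES = (0.0, 152.0, 162.0, 250.0)     # cm

# marginal component models: mean(sex, age, height) and SD on the raw scale
_COMPONENT_MODELS = {
    "waist": (lambda male, age, h: 60.0 + 2.2 * (age - 11.0) + 1.5 * male,
              10.5),
    "sbp": (lambda male, age, h: 97.0 + 1.8 * (age - 11.0) + 1.0 * male
            + 0.08 * (h - 158.0), 8.5),
    "hdl": (lambda male, age, h: 58.0 - 0.5 * (age - 11.0) - 0.5 * male,
            13.0),
    "triglycerides": (lambda male, age, h: 64.0 + 1.2 * (age - 11.0)
                      + 5.0 * (1 - male), 30.0),
    # HOMA-IR keeps a Gaussian marginal so planted effects stay linear on
    # the raw scale; the SD is kept small enough that the positivity floor
    # is almost never hit (a wider, skewed marginal would truncate ~10% of
    # draws and distort planted linear effects).
    "homa_ir": (lambda male, age, h: 2.2 + 0.25 * (age - 11.0)
                + 0.6 * (1 - male), 1.2),
}

RACE_LEVELS = ("black", "hispanic", "white", "asian", "multiple")
RACE_PROBS = (0.15, 0.04, 0.64, 0.03, 0.14)
SMOKING_LEVELS = ("never", "former", "during_pregnancy")
SMOKING_PROBS = (0.70, 0.20, 0.10)


def _draw_demographics(rng, sexes: np.ndarray) -> pd.DataFrame:
    n = len(sexes)
    male = (sexes == "male").astype(float)
    age = np.clip(rng.normal(12.9, 0.65, n), 11.5, 15.5)
    height = np.clip(rng.normal(158.0 + 2.0 * male, 7.5), 135.0, 185.0)
    return pd.DataFrame({"sex": sexes, "age_years": age, "height_cm": height,
                         "male": male})


def _component_values(rng, demo: pd.DataFrame, z: dict[str, np.ndarray]
                      ) -> pd.DataFrame:
    """Raw-scale component measurements from component z-signals."""
    male = demo["male"].to_numpy()
    age = demo["age_years"].to_numpy()
    height = demo["height_cm"].to_numpy()
    n = len(demo)
    out = {}
    for comp, (mean_fn, sd) in _COMPONENT_MODELS.items():
        out[comp] = mean_fn(male, age, height) + sd * z[comp]
    # positivity floors sit >2.5 SD below the means so the planted linear
    # structure is essentially never truncated
    waist = np.clip(out["waist"], 40.0, None)
    sbp_true = out["sbp"]
    hdl = np.clip(out["hdl"], 5.0, None)
    tg = np.clip(out["triglycerides"], 1.0, None)
    homa = np.clip(out["homa_ir"], 0.05, None)
    glucose = np.clip(rng.normal(88.0, 6.0, n), 60.0, 140.0)
    insulin = homa * 405.0 / glucose
    df = pd.DataFrame({
        "waist_cm": waist,
        "hdl_mgdl": hdl,
        "triglycerides_mgdl": tg,
        "glucose_mgdl": glucose,
        "insulin_uiu_ml": insulin,
    })
    for r in range(1, 6):
        df[f"sbp_{r}"] = sbp_true + rng.normal(0.0, 2.0, n)
    return df


def _null_z(rng, n: int, noise_sd: float) -> dict[str, np.ndarray]:
    return {c: rng.normal(0.0, noise_sd, n) for c in COMPONENT_NAMES}


def build_reference_tables(config: SimulationConfig, rng,
                           return_population: bool = False):
    """Mean/SD tables per component by sex and age bin (plus height bins
    for SBP), estimated from an independently simulated null reference
    population of ``config.n_reference`` adolescents.  With
    ``return_population`` the raw reference population is returned too
    (useful for self-standardization checks)."""
    n = config.n_reference
    sexes = np.array(["male", "female"])[rng.integers(0, 2, n)]
    demo = _draw_demographics(rng, sexes)
    comp = _component_values(rng, demo, _null_z(rng, n, config.mets_noise_sd))
    comp["homa_ir"] = comp["glucose_mgdl"] * comp["insulin_uiu_ml"] / 405.0
    comp["sbp"] = comp[[f"sbp_{r}" for r in range(1, 6)]].mean(axis=1)
    comp["waist"] = comp["waist_cm"]
    comp["hdl"] = comp["hdl_mgdl"]
    comp["triglycerides"] = comp["triglycerides_mgdl"]
    comp["sex"] = demo["sex"].to_numpy()
    comp["age_years"] = demo["age_years"].to_numpy()
    comp["height_cm"] = demo["height_cm"].to_numpy()

    rows = []
    for component in COMPONENT_NAMES:
        height_edges = (SBP_HEIGHT_BIN_EDGES if component == "sbp"
                        else (None,))
        for sex in ("male", "female"):
            sub = comp[comp["sex"] == sex]
            for i in range(len(AGE_BIN_EDGES) - 1):
                lo, hi = AGE_BIN_EDGES[i], AGE_BIN_EDGES[i + 1]
                in_age = sub[(sub["age_years"] >= lo)
                             & (sub["age_years"] < hi)]
                if component == "sbp":
                    for j in range(len(SBP_HEIGHT_BIN_EDGES) - 1):
                        hlo = SBP_HEIGHT_BIN_EDGES[j]
                        hhi = SBP_HEIGHT_BIN_EDGES[j + 1]
                        cell = in_age[(in_age["height_cm"] >= hlo)
                                      & (in_age["height_cm"] < hhi)]
                        if len(cell) < 2:
                            continue
                        rows.append((component, sex, lo, hi, hlo, hhi,
                                     cell[component].mean(),
                                     cell[component].std(ddof=1)))
                else:
                    if len(in_age) < 2:
                        continue
                    rows.append((component, sex, lo, hi, np.nan, np.nan,
                                 in_age[component].mean(),
                                 in_age[component].std(ddof=1)))
    ref = pd.DataFrame(rows, columns=["component", "sex", "age_bin_lo",
                                      "age_bin_hi", "height_bin_lo",
                                      "height_bin_hi", "mean", "sd"])
    if (ref["sd"] <= 0).any():
        raise RuntimeError("degenerate reference stratum with zero SD")
    if return_population:
        population = comp[[f"sbp_{r}" for r in range(1, 6)]
                          + ["waist_cm", "hdl_mgdl", "triglycerides_mgdl",
                             "glucose_mgdl", "insulin_uiu_ml",
                             "sex", "age_years", "height_cm"]].copy()
        population.insert(0, "subject_id",
                          [f"R{i + 1:06d}" for i in range(n)])
        return ref, population
    return ref


def simulate_outcomes_and_references(config: SimulationConfig,
                                     truth: GroundTruth,
                                     factors: pd.DataFrame, rng,
                                     reference: pd.DataFrame | None = None
                                     ) -> tuple[pd.DataFrame, pd.DataFrame,
                                                pd.DataFrame]:
    """MetS component table, reference tables, and covariate table.

    Each component z-signal is the configured linear combination of planted
    module factors and (within-sex standardized) milestone exposures plus
    Gaussian noise; raw measurements place that z on each component's
    marginal scale.  Reference tables come from a large independent null
    population with the same marginal model (pass ``reference`` to reuse a
    precomputed table, e.g. across replicate simulations).
    """
    mil = truth.milestones
    n = len(mil)
    demo = _draw_demographics(rng, mil["sex"].to_numpy())

    z = _null_z(rng, n, config.mets_noise_sd)
    for eff in config.effect_map:
        if eff.target.startswith("module_"):
            continue
        if eff.exposure.startswith("module_"):
            x = factors[eff.exposure].to_numpy()
        else:
            x = _standardized_exposure(mil, eff.exposure,
                                       eff.stratum).to_numpy()
        if eff.stratum == "both":
            mask = np.ones(n, dtype=bool)
        else:
            mask = (mil["sex"] == eff.stratum).to_numpy()
        targets = ([eff.target] if eff.target != "composite"
                   else list(COMPONENT_NAMES))
        for comp in targets:
            sign = -1.0 if (eff.target == "composite" and comp == "hdl") \
                else 1.0
            z[comp][mask] += sign * eff.beta * x[mask]

    comp = _component_values(rng, demo, z)
    comp.insert(0, "subject_id", mil["subject_id"].to_numpy())
    comp.insert(1, "sex", mil["sex"].to_numpy())
    comp.insert(2, "age_years", demo["age_years"].to_numpy())
    comp.insert(3, "height_cm", demo["height_cm"].to_numpy())

    if reference is None:
        reference = build_reference_tables(config, rng)

    male = demo["male"].to_numpy()
    puberty_p = np.where(male[:, None] == 1,
                         [[0.15, 0.40, 0.30, 0.15]],
                         [[0.05, 0.15, 0.35, 0.45]])
    puberty = np.array([rng.choice([1, 2, 3, 4], p=p) for p in puberty_p])
    covariates = pd.DataFrame({
        "subject_id": mil["subject_id"].to_numpy(),
        "sex": mil["sex"].to_numpy(),
        "age_years": demo["age_years"].to_numpy(),
        "height_cm": demo["height_cm"].to_numpy(),
        "race_ethnicity": rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS),
        "puberty_score": puberty,
        "maternal_college": rng.choice([1, 0], size=n, p=[0.70, 0.30]),
        "prepreg_bmi": np.clip(rng.normal(24.8, 5.2, n), 15.0, 50.0),
        "smoking": rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS),
    })
    return comp, reference, covariates


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None,
                    reference: pd.DataFrame | None = None
                    ) -> SyntheticDataset:
    """Run the full generator under one seed and return all tables."""
    config = SimulationConfig() if config is None else config
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    anthro, truth = simulate_trajectories(config, rng)
    matrix, meta, factors = simulate_metabolome(config, truth, rng)
    comps, reference, covariates = simulate_outcomes_and_references(
        config, truth, factors, rng, reference=reference)
    return SyntheticDataset(anthropometry=anthro, metabolites=matrix,
                            metabolite_meta=meta, mets_components=comps,
                            reference_tables=reference,
                            covariates=covariates, ground_truth=truth,
                            config=config)


def write_dataset(dataset: SyntheticDataset, directory, overwrite=False
                  ) -> dict[str, Path]:
    """Write all cohort tables plus ground_truth.json to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "anthropometry.csv": dataset.anthropometry,
        "metabolites.csv": dataset.metabolites.reset_index(),
        "metabolite_meta.csv": dataset.metabolite_meta,
        "mets_components.csv": dataset.mets_components,
        "reference_tables.csv": dataset.reference_tables,
        "covariates.csv": dataset.covariates,
    }
    paths = {}
    for fname in list(tables) + ["ground_truth.json"]:
        path = directory / fname
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
    for fname, df in tables.items():
        path = directory / fname
        df.to_csv(path, index=False)
        paths[fname] = path
    gt_path = directory / "ground_truth.json"
    payload = dataset.ground_truth.to_dict()
    payload["config"] = config_to_dict(dataset.config)
    gt_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["ground_truth.json"] = gt_path
    return paths
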