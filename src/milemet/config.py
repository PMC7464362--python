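"""Configuration objects for the simulator, growth model, and network stages.

All stages are driven by small frozen-ish dataclasses with explicit
validation so that a pipeline run is fully described by one YAML file
plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass
class Effect:
    """One planted causal edge in the synthetic cohort.

    exposure : milestone name ('age_peak', 'bmi_peak', 'age_rebound',
        'bmi_rebound') or a module factor ('module_1', ...).
    target : module factor ('module_k'), a MetS component
        ('waist', 'sbp', 'hdl', 'triglycerides', 'homa_ir'), or
        'composite' (applied to all five components, HDL reversed).
    beta : effect size per 1 SD of the exposure, on the z scale of the
        target (module factors and component z-scores both have unit SD).
    stratum : 'male', 'female' or 'both'.
    """

    exposure: str
    target: str
    beta: float
    stratum: str = "both"

    def applies_to(self, sex: str) -> bool:
        return self.stratum in ("both", sex)


MILESTONE_NAMES = ("age_peak", "bmi_peak", "age_rebound", "bmi_rebound")
COMPONENT_NAMES = ("waist", "sbp", "hdl", "triglycerides", "homa_ir")

#: Default visit schedule in months.  Twelve visits from two weeks to five
#: years, dense around the infancy peak (~8 mo) and spanning the childhood
#: rebound (~3.5 y).  The quartic latent-curve family used by the simulator
#: steepens rapidly beyond ~1.5x the rebound age, so the schedule ends at
#: 60 mo rather than deep into mid-childhood; see docs/methods.md.
DEFAULT_MEASUREMENT_AGES = (0.5, 2.0, 4.0, 6.0, 8.0, 10.5, 13.5, 18.0,
                            24.0, 32.0, 44.0, 60.0)

#: Default planted path: earlier rebound -> higher module-2 factor -> higher
#: metabolic risk, in boys (the configuration the screen is meant to detect).
#: Sized so the implied total milestone->MetS effect is ~0.3-0.4 SD per SD
#: after milestone-estimation attenuation, the scale reported for rebound
#: age in adolescent cohorts.
DEFAULT_EFFECTS = (
    Effect("age_rebound", "module_2", -0.7, "male"),
    Effect("module_2", "composite", 0.6, "male"),
)


@dataclass
class SimulationConfig:
    """Ground-truth generating model for one synthetic cohort."""

    n_per_sex: int = 150
    measurement_ages: Sequence[float] = DEFAULT_MEASUREMENT_AGES

    # infancy BMI peak (months, kg/m^2)
    peak_age_mean: float = 8.4
    peak_age_sd: float = 1.5
    peak_age_bounds: tuple[float, float] = (5.0, 12.5)
    peak_magnitude_mean: float = 18.1
    peak_magnitude_sd: float = 1.35

    # childhood BMI rebound (months); drop = B_p - B_r (kg/m^2)
    rebound_age_mean: float = 42.0
    rebound_age_sd: float = 5.0
    rebound_age_bounds: tuple[float, float] = (34.0, 53.0)
    drop_mean: float = 2.5
    drop_sd: float = 0.5
    drop_bounds: tuple[float, float] = (1.2, 4.0)

    #: third root of the latent-curve derivative sits at -c (months);
    #: positive c gives a positive slope at birth and controls how much of
    #: the curve's movement happens before the peak (larger c -> more
    #: pronounced infancy peak relative to the peak-to-rebound drop).
    curve_c: float = 90.0
    bmi_noise_sd: float = 0.3

    # metabolome
    module_sizes: Sequence[int] = (30, 30, 30, 30, 30)
    intra_module_loading: float = 0.8
    n_background_metabolites: int = 60
    lod_censor_fraction: float = 0.1
    nonendogenous_fraction: float = 0.10

    # outcomes
    effect_map: Sequence[Effect] = DEFAULT_EFFECTS
    mets_noise_sd: float = 1.0
    n_reference: int = 20_000

    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_metabolites(self) -> int:
        return int(sum(self.module_sizes)) + int(self.n_background_metabolites)

    def validate(self) -> None:
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")
        ages = list(self.measurement_ages)
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ValueError("measurement_ages must be strictly increasing")
        if not self.peak_age_mean < self.rebound_age_mean:
            raise ValueError("peak_age_mean must be < rebound_age_mean")
        for name in ("peak_age_sd", "peak_magnitude_sd", "rebound_age_sd",
                     "drop_sd", "bmi_noise_sd", "mets_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.intra_module_loading < 1:
            if self.intra_module_loading != 0:
                raise ValueError("intra_module_loading must be in [0, 1)")
        if not 0 <= self.lod_censor_fraction <= 0.5:
            raise ValueError("lod_censor_fraction must be in [0, 0.5]")
        if not 0 <= self.nonendogenous_fraction < 1:
            raise ValueError("nonendogenous_fraction must be in [0, 1)")
        if any(int(m) < 1 for m in self.module_sizes):
            raise ValueError("module_sizes must be positive")
        if self.curve_c <= 0:
            raise ValueError("curve_c must be > 0")
        for eff in self.effect_map:
            if eff.stratum not in ("male", "female", "both"):
                raise ValueError(f"unknown stratum {eff.stratum!r}")
            if eff.exposure.startswith("module_"):
                if int(eff.exposure.split("_")[1]) > self.n_modules:
                    raise ValueError(f"effect exposure {eff.exposure!r} "
                                     "references an unknown module")
            elif eff.exposure not in MILESTONE_NAMES:
                raise ValueError(f"unknown effect exposure {eff.exposure!r}")
            if eff.target.startswith("module_"):
                if int(eff.target.split("_")[1]) > self.n_modules:
                    raise ValueError(f"effect target {eff.target!r} "
                                     "references an unknown module")
            elif eff.target not in COMPONENT_NAMES + ("composite",):
                raise ValueError(f"unknown effect target {eff.target!r}")


@dataclass
class SplineConfig:
    """Natural-cubic-spline basis for the BMI growth model.

    Knots are in months.  The basis needs at least 4 interior knots so a
    fitted subject curve can carry two interior stationary points (the
    infancy peak and the childhood rebound).
    """

    interior_knots: Sequence[float] = (3.0, 8.0, 14.0, 22.0, 34.0, 48.0)
    boundary_knots: tuple[float, float] = (0.25, 61.0)
    #: number of leading basis terms (after the intercept) that receive
    #: subject-level random coefficients; None = all basis terms.  With the
    #: local B-spline natural basis, per-term random coefficients act on
    #: separate age regions.
    n_random_basis: int | None = None
    #: covariance of the random coefficients: 'diagonal' keeps one variance
    #: per term (tractable for the full basis), 'unstructured' estimates
    #: the full covariance (use with few random terms).
    random_structure: str = "diagonal"

    def validate(self) -> None:
        lo, hi = self.boundary_knots
        knots = list(self.interior_knots)
        if len(knots) < 4:
            raise ValueError("need >= 4 interior knots for two stationary points")
        if sorted(knots) != knots or len(set(knots)) != len(knots):
            raise ValueError("interior knots must be strictly increasing")
        if not (lo < knots[0] and knots[-1] < hi):
            raise ValueError("interior knots must lie inside the boundary knots")
        if self.n_random_basis is not None and self.n_random_basis < 1:
            raise ValueError("n_random_basis must be >= 1 or None")
        if self.random_structure not in ("diagonal", "unstructured"):
            raise ValueError("random_structure must be 'diagonal' or "
                             "'unstructured'")

    @property
    def n_basis(self) -> int:
        # natural cubic spline with K total knots has K-1 basis functions
        # (excluding the intercept)
        return len(self.interior_knots) + 1


@dataclass
class MilestoneWindows:
    """Age windows (months) searched for each milestone."""

    infancy: tuple[float, float] = (0.5, 20.0)
    childhood: tuple[float, float] = (24.0, 110.0)


@dataclass
class NetworkConfig:
    """Consensus weighted-correlation-network parameters."""

    soft_power: float = 10.0
    min_module_size: int = 20
    #: where to cut the dendrogram before branch decomposition: 'gap' cuts
    #: at the largest jump in sorted merge heights (separates coherent
    #: branches from the near-ceiling merges that attach background
    #: metabolites), 'quantile' cuts at ``cut_height_quantile`` of the
    #: merge heights.
    cut_method: str = "gap"
    cut_height_quantile: float = 0.99
    #: a branch is accepted as a module only if its median internal
    #: topological overlap exceeds its mean overlap with the rest of the
    #: network by this factor.  Branches assembled from noise reach ~2 by
    #: linkage selection alone; coherent factor-driven modules exceed ~4
    #: even at weak loadings, so 3 separates the regimes.
    min_cohesion: float = 3.0
    calibration_quantile: float | None = 0.95
    outlier_z_threshold: float = -2.5

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.cut_height_quantile <= 1:
            raise ValueError("cut_height_quantile must be in (0, 1]")
        if self.cut_method not in ("gap", "quantile"):
            raise ValueError("cut_method must be 'gap' or 'quantile'")
        if self.calibration_quantile is not None and not (
                0 < self.calibration_quantile <= 1):
            raise ValueError("calibration_quantile must be in (0, 1] or None")
        if self.min_cohesion < 1:
            raise ValueError("min_cohesion must be >= 1")


@dataclass
class ScreenConfig:
    """Meet-in-the-middle screen settings."""

    q_fdr: float = 0.05
    alpha: float = 0.05
    #: 'joint' = one BH family per sex across all carried milestones x modules
    fdr_family: str = "joint"

    def validate(self) -> None:
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fdr_family not in ("joint", "per_milestone"):
            raise ValueError("fdr_family must be 'joint' or 'per_milestone'")


def config_to_dict(cfg) -> dict:
    """Dataclass -> plain dict (for manifests and YAML round-trips)."""
    d = asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
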