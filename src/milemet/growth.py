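"""BMI growth-milestone estimation.

Fits a sex-interacted natural-cubic-spline mixed model to longitudinal BMI
and extracts, per subject, the age and magnitude of the infancy BMI peak
(the interior maximum of the fitted curve) and the childhood BMI rebound
(the interior minimum), defined as the points where the fitted curve's
slope equals zero.

The spline basis is the truncated-power natural cubic basis with linear
tails beyond the boundary knots; its derivative is piecewise quadratic and
available in closed form, so stationary points are located by bracketing
derivative sign changes on a fine grid and refining with bisection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import MilestoneWindows, SplineConfig

logger = logging.getLogger(__name__)

MID_CHILDHOOD_MONTHS = 132.0
_ROOT_GRID_STEP = 0.1       # months
_ROOT_TOL = 1e-3            # months


class NaturalSplineBasis:
    """Natural cubic spline basis of age with analytic first derivative.

    Built from the cubic B-spline basis on the given knots with the two
    natural constraints (zero second derivative at each boundary knot)
    imposed through a locality-preserving null-space transform: the
    constraints only touch the three boundary-adjacent B-splines at each
    end, so every resulting basis function keeps compact support.  This
    matters for the mixed model: subject-level random coefficients on the
    basis act on separate age regions instead of leaking across the whole
    trajectory.  The constant function lies in the span, so the first
    column is dropped in favour of the model's explicit intercept.
    Derivatives come from the exact B-spline derivative.
    """

    def __init__(self, config: SplineConfig):
        from scipy.interpolate import BSpline

        config.validate()
        self.config = config
        lo, hi = config.boundary_knots
        interior = np.asarray(config.interior_knots, dtype=float)
        self.knots = np.concatenate([[lo], interior, [hi]])
        tk = np.concatenate([[lo] * 4, interior, [hi] * 4])
        n_b = len(interior) + 4
        self._spline = BSpline(tk, np.eye(n_b), 3, extrapolate=False)
        self._dspline = self._spline.derivative()
        d2 = BSpline(tk, np.eye(n_b), 3, extrapolate=True).derivative(2)
        c_lo = d2(lo)   # support on first three B-splines
        c_hi = d2(hi)   # support on last three B-splines
        T = np.zeros((n_b, n_b - 2))
        T[:3, :2] = _null_basis(c_lo[:3])
        for j in range(3, n_b - 3):
            T[j, j - 1] = 1.0
        T[-3:, -2:] = _null_basis(c_hi[-3:])
        # drop the first column; the constant is carried by the intercept
        self._transform = T[:, 1:]
        grid = np.linspace(lo, hi, 201)
        raw = self._spline(grid) @ self._transform
        self.scales = raw.max(axis=0) - raw.min(axis=0)
        if not np.all(self.scales > 1e-12):
            raise ValueError("degenerate spline basis (coincident knots?)")

    @property
    def n_basis(self) -> int:
        return self._transform.shape[1]

    def design(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self._spline(t) @ self._transform) / self.scales

    def derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self._dspline(t) @ self._transform) / self.scales

    def check_domain(self, t) -> None:
        t = np.asarray(t, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        if (t < lo).any() or (t > hi).any():
            raise ValueError(f"ages outside boundary knots [{lo}, {hi}]; "
                             "extrapolation is not supported")


def _null_basis(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3 x 2) of the null space of a 1 x 3 constraint."""
    _, _, vt = np.linalg.svd(c.reshape(1, -1))
    return vt[1:].T


@dataclass
class MilestoneEstimate:
    subject_id: str
    age_peak: float
    bmi_peak: float
    age_rebound: float
    bmi_rebound: float
    peak_identified: bool
    rebound_identified: bool


def eligibility_filter(records: pd.DataFrame, min_measurements: int = 3,
                       max_age_months: float = MID_CHILDHOOD_MONTHS
                       ) -> pd.DataFrame:
    """Retain subjects with >= ``min_measurements`` BMI values from birth
    through mid-childhood; returns the filtered long table."""
    if len(records) == 0:
        raise ValueError("empty anthropometry table")
    in_window = records[records["age_months"] <= max_age_months]
    counts = in_window.groupby("subject_id").size()
    keep = counts[counts >= min_measurements].index
    dropped = records["subject_id"].nunique() - len(keep)
    logger.info("eligibility filter: %d subjects retained, %d excluded",
                len(keep), dropped)
    return records[records["subject_id"].isin(keep)].copy()


class GrowthCurveModel:
    """Sex-interacted natural-spline mixed model for BMI trajectories.

    Parameters
    ----------
    spline : SplineConfig, optional
        Knot placement and the number of leading basis terms that receive
        subject-level random coefficients (random intercept always
        included, unstructured covariance).
    windows : MilestoneWindows, optional
        Infancy and childhood age windows searched for stationary points.

    Fitted attributes (trailing underscore) follow scikit-learn
    conventions; ``fit`` expects the long anthropometry table.
    """

    def __init__(self, spline: SplineConfig | None = None,
                 windows: MilestoneWindows | None = None,
                 sex_interactions: bool = True):
        self.spline = spline or SplineConfig()
        self.windows = windows or MilestoneWindows()
        self.sex_interactions = sex_interactions

    def get_params(self, deep=True):
        return {"spline": self.spline, "windows": self.windows,
                "sex_interactions": self.sex_interactions}

    def set_params(self, **params):
        for key, val in params.items():
            setattr(self, key, val)
        return self

    # -- fitting -----------------------------------------------------------

    def _design(self, ages: np.ndarray, male: np.ndarray) -> np.ndarray:
        N = self.basis_.design(ages)
        cols = [np.ones((len(ages), 1)), male[:, None], N]
        if self.sex_interactions:
            cols.append(N * male[:, None])
        return np.hstack(cols)

    def fit(self, records: pd.DataFrame):
        records = records.sort_values(["subject_id", "age_months"],
                                      kind="mergesort").reset_index(drop=True)
        self.basis_ = NaturalSplineBasis(self.spline)
        sexes = records.groupby("subject_id")["sex"].first()
        if self.sex_interactions and sexes.nunique() < 2:
            raise ValueError("sex interactions requested but only one sex "
                             "present in the data")
        ages = records["age_months"].to_numpy(dtype=float)
        self.basis_.check_domain(ages)
        male = (records["sex"] == "male").to_numpy(dtype=float)
        y = records["bmi"].to_numpy(dtype=float)
        X = self._design(ages, male)

        q = (self.basis_.n_basis if self.spline.n_random_basis is None
             else min(self.spline.n_random_basis, self.basis_.n_basis))
        self._n_random = q
        Z = np.hstack([np.ones((len(ages), 1)),
                       self.basis_.design(ages)[:, :q]])
        groups = records["subject_id"].to_numpy()

        self.subject_sex_ = sexes.to_dict()
        self.age_range_ = (float(ages.min()), float(ages.max()))

        # Degenerate noiseless case: if the fixed design interpolates the
        # data exactly, REML is undefined (zero residual variance); fall
        # back to the exact least-squares solution with zero deviations.
        beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        if np.abs(resid).max() < 1e-8:
            self.fe_params_ = beta_ols
            self.random_effects_ = {s: np.zeros(q + 1)
                                    for s in sexes.index}
            self.scale_ = 0.0
            self.converged_ = True
            self.result_ = None
            return self

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
            fit_kwargs = {"reml": True, "maxiter": 500}
            if self.spline.random_structure == "diagonal":
                from statsmodels.regression.mixed_linear_model import \
                    MixedLMParams
                fit_kwargs["free"] = MixedLMParams.from_components(
                    fe_params=np.ones(X.shape[1]), cov_re=np.eye(q + 1))
            result = model.fit(method="lbfgs", **fit_kwargs)
            if not result.converged:
                result = model.fit(method="powell", **fit_kwargs)
        self.result_ = result
        self.converged_ = bool(result.converged)
        if not self.converged_:
            logger.warning("mixed model did not converge; estimates flagged")
        self.fe_params_ = np.asarray(result.fe_params)
        self.random_effects_ = {g: np.asarray(re)[: q + 1]
                                for g, re in result.random_effects.items()}
        self.scale_ = float(result.scale)
        return self

    def _check_fitted(self):
        if not hasattr(self, "fe_params_"):
            raise RuntimeError("model is not fitted")

    # -- prediction --------------------------------------------------------

    def _fixed_coef(self, sex: str) -> tuple[float, np.ndarray]:
        """Intercept and spline coefficients for a given sex."""
        p = self.basis_.n_basis
        male = 1.0 if sex == "male" else 0.0
        beta = self.fe_params_
        intercept = beta[0] + beta[1] * male
        coef = beta[2:2 + p].copy()
        if self.sex_interactions:
            coef = coef + male * beta[2 + p:2 + 2 * p]
        return intercept, coef

    def predict_curve(self, subject_id, ages):
        """Fitted BMI values and analytic first derivative for one subject."""
        self._check_fitted()
        if subject_id not in self.subject_sex_:
            raise KeyError(f"unknown subject {subject_id!r}")
        ages = np.asarray(ages, dtype=float)
        self.basis_.check_domain(ages)
        sex = self.subject_sex_[subject_id]
        intercept, coef = self._fixed_coef(sex)
        u = self.random_effects_[subject_id]
        N = self.basis_.design(ages)
        dN = self.basis_.derivative(ages)
        q = self._n_random
        bmi = intercept + N @ coef + u[0] + N[:, :q] @ u[1:]
        deriv = dN @ coef + dN[:, :q] @ u[1:]
        return bmi, deriv

    def population_curve(self, sex: str, ages):
        self._check_fitted()
        ages = np.asarray(ages, dtype=float)
        self.basis_.check_domain(ages)
        intercept, coef = self._fixed_coef(sex)
        N = self.basis_.design(ages)
        dN = self.basis_.derivative(ages)
        return intercept + N @ coef, dN @ coef

    # -- milestones --------------------------------------------------------

    def _stationary_points(self, subject_id, window):
        lo = max(window[0], self.basis_.knots[0], self.age_range_[0])
        hi = min(window[1], self.basis_.knots[-1], self.age_range_[1])
        if hi <= lo:
            return []
        grid = np.arange(lo, hi + _ROOT_GRID_STEP / 2, _ROOT_GRID_STEP)
        _, d = self.predict_curve(subject_id, grid)
        sign = np.sign(d)
        roots = []
        for i in np.flatnonzero(np.diff(sign) != 0):
            a, b = grid[i], grid[i + 1]
            da, db = d[i], d[i + 1]
            if da == 0:
                roots.append((a, "max" if db < 0 else "min"))
                continue
            while b - a > _ROOT_TOL:
                mid = 0.5 * (a + b)
                dm = self.predict_curve(subject_id, [mid])[1][0]
                if np.sign(dm) == np.sign(da):
                    a, da = mid, dm
                else:
                    b = mid
            roots.append((0.5 * (a + b), "max" if da > 0 else "min"))
        return roots

    def extract_milestones(self, subject_id) -> MilestoneEstimate:
        """Locate the infancy peak and childhood rebound of one subject's
        fitted curve; non-identification is flagged, never an error."""
        self._check_fitted()
        peak_age = peak_bmi = reb_age = reb_bmi = np.nan
        peak_found = reb_found = False

        maxima = [(t, self.predict_curve(subject_id, [t])[0][0])
                  for t, kind in
                  self._stationary_points(subject_id, self.windows.infancy)
                  if kind == "max"]
        if maxima:
            peak_age, peak_bmi = max(maxima, key=lambda r: r[1])
            peak_found = True

        minima = [(t, self.predict_curve(subject_id, [t])[0][0])
                  for t, kind in
                  self._stationary_points(subject_id, self.windows.childhood)
                  if kind == "min"]
        if minima:
            reb_age, reb_bmi = min(minima, key=lambda r: r[1])
            reb_found = True

        return MilestoneEstimate(subject_id, peak_age, peak_bmi,
                                 reb_age, reb_bmi, peak_found, reb_found)

    def extract_all_milestones(self) -> pd.DataFrame:
        self._check_fitted()
        rows = []
        for sid in self.subject_sex_:
            est = self.extract_milestones(sid)
            rows.append({"subject_id": sid, "sex": self.subject_sex_[sid],
                         "age_peak": est.age_peak, "bmi_peak": est.bmi_peak,
                         "age_rebound": est.age_rebound,
                         "bmi_rebound": est.bmi_rebound,
                         "peak_identified": est.peak_identified,
                         "rebound_identified": est.rebound_identified})
        return pd.DataFrame(rows)


def fit_growth_model(records: pd.DataFrame,
                     spline: SplineConfig | None = None,
                     windows: MilestoneWindows | None = None
                     ) -> GrowthCurveModel:
    """Convenience wrapper: eligibility filter + mixed-model fit."""
    eligible = eligibility_filter(records)
    return GrowthCurveModel(spline=spline, windows=windows).fit(eligible)


def standardize_exposures(milestones: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale the four milestone exposures to per-within-sex-SD units.

    Returns the scaled table plus the SDs used (reported alongside results,
    e.g. '1 SD age at rebound = 21.4 mo').  Subjects with a non-identified
    milestone keep NaN for that exposure.
    """
    exposures = ["age_peak", "bmi_peak", "age_rebound", "bmi_rebound"]
    scaled = milestones.copy()
    sds = []
    for sex in ("male", "female"):
        mask = milestones["sex"] == sex
        if mask.sum() == 0:
            continue
        for col in exposures:
            vals = milestones.loc[mask, col]
            n_obs = vals.notna().sum()
            if n_obs < 2:
                raise ValueError(f"fewer than 2 identified {col!r} values "
                                 f"for sex {sex!r}")
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero SD for exposure {col!r} ({sex})")
            scaled.loc[mask, col] = vals / sd
            sds.append({"sex": sex, "exposure": col, "sd": sd, "n": n_obs})
    return scaled, pd.DataFrame(sds)
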