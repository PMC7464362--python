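"""Three-step screen: OLS association fits, BH-FDR, carried sets, the
component follow-up, and the mutual-adjustment sensitivity analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from milemet import (ScreenConfig, bh_fdr, fit_linear_association, run_screen,
                     run_step1, run_step2, run_step3,
                     sensitivity_mutual_adjustment)
from milemet.screen import MODEL1


def bh_exhaustive(p, q):
    """Literal step-up definition: reject the k smallest p-values where
    k = max{i : p_(i) <= i q / m}."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


class TestBhFdr:
    def test_hand_evaluated_example(self):
        p = [0.001, 0.004, 0.03, 0.1, 0.9]
        np.testing.assert_array_equal(bh_fdr(p, 0.05),
                                      [True, True, True, False, False])

    def test_all_ones_rejects_nothing(self):
        assert not bh_fdr([1.0] * 6, 0.05).any()

    def test_empty_input(self):
        assert bh_fdr([], 0.05).size == 0

    def test_matches_exhaustive_definition_on_permutations(self):
        base_sets = [(0.01, 0.02, 0.04, 0.2), (0.001, 0.049, 0.05, 0.9, 0.3),
                     (0.012, 0.025, 0.037, 0.04, 0.11, 0.5, 0.7, 0.9)]
        for base in base_sets:
            for perm in itertools.permutations(base):
                np.testing.assert_array_equal(bh_fdr(perm, 0.05),
                                              bh_exhaustive(perm, 0.05))

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            expected = multipletests(p, 0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(bh_fdr(p, 0.05), expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


def make_screen_data(rng, n=200, beta_a=0.0, beta_b=0.0):
    """Small analysis frame: milestones, two MEs, MetS z, covariates."""
    sex = np.repeat(["male", "female"], n // 2)
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "sex": sex,
        "age_peak": rng.normal(size=n),
        "bmi_peak": rng.normal(size=n),
        "age_rebound": rng.normal(size=n),
        "bmi_rebound": rng.normal(size=n),
        "age_years": rng.normal(12.9, 0.6, n),
        "race_ethnicity": rng.choice(list("abcde"), n),
        "puberty_score": rng.integers(1, 5, n),
        "maternal_college": rng.integers(0, 2, n),
        "prepreg_bmi": rng.normal(25, 4, n),
        "smoking": rng.choice(["never", "former", "during"], n),
    })
    df["ME1"] = beta_a * df.age_rebound + rng.normal(size=n)
    df["ME2"] = rng.normal(size=n)
    df["mets_z"] = beta_b * df.ME1 + rng.normal(scale=0.5, size=n)
    for comp in ("z_waist", "z_homa_ir", "z_hdl", "z_triglycerides",
                 "z_sbp"):
        df[comp] = rng.normal(size=n)
    return df


class TestFitLinearAssociation:
    def test_noiseless_identity(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 2.0 * df.x
        res = fit_linear_association(df, "y", "x")
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.ci_hi - res.ci_lo == pytest.approx(0.0, abs=1e-8)
        assert res.n == 50

    def test_matches_statsmodels_formula_oracle(self, rng):
        import statsmodels.formula.api as smf
        df = make_screen_data(rng)
        res = fit_linear_association(df, "mets_z", "age_rebound",
                                     ("age_years", "race_ethnicity"))
        oracle = smf.ols("mets_z ~ age_rebound + age_years"
                         " + C(race_ethnicity)", data=df).fit()
        assert res.beta == pytest.approx(oracle.params["age_rebound"])
        assert res.p == pytest.approx(oracle.pvalues["age_rebound"])
        lo, hi = oracle.conf_int().loc["age_rebound"]
        assert res.ci_lo == pytest.approx(lo)
        assert res.ci_hi == pytest.approx(hi)

    def test_ci_coverage_at_planted_beta(self):
        hits = 0
        reps = 400
        for rep in range(reps):
            r = np.random.default_rng(rep)
            x = r.normal(size=250)
            y = 0.5 * x + r.normal(size=250)
            res = fit_linear_association(pd.DataFrame({"x": x, "y": y}),
                                         "y", "x")
            hits += res.ci_lo <= 0.5 <= res.ci_hi
        assert 0.93 <= hits / reps <= 0.97

    def test_constant_outcome_raises(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": 1.0})
        with pytest.raises(ValueError, match="constant"):
            fit_linear_association(df, "y", "x")

    def test_rank_deficient_names_aliased_terms(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = rng.normal(size=30)
        df["x2"] = 2.0 * df.x
        with pytest.raises(ValueError, match="x2"):
            fit_linear_association(df, "y", "x", ("x2",))

    def test_exposure_in_covariates_rejected(self, rng):
        df = make_screen_data(rng)
        with pytest.raises(ValueError):
            fit_linear_association(df, "mets_z", "age_peak", ("age_peak",))

    def test_complete_case_n_shrinks_with_missing_covariates(self, rng):
        df = make_screen_data(rng)
        df.loc[:4, "puberty_score"] = np.nan
        a = fit_linear_association(df, "mets_z", "ME1", ())
        b = fit_linear_association(df, "mets_z", "ME1",
                                   ("age_years", "race_ethnicity"))
        c = fit_linear_association(df, "mets_z", "ME1",
                                   ("age_years", "race_ethnicity",
                                    "puberty_score"))
        assert a.n >= b.n >= c.n
        assert c.n == a.n - 5


class TestSteps:
    def test_step1_table_shape(self, rng):
        df = make_screen_data(rng)
        mil = df[["subject_id", "sex", "age_peak", "bmi_peak", "age_rebound",
                  "bmi_rebound"]]
        mets = df[["subject_id", "mets_z", "z_waist", "z_homa_ir", "z_hdl",
                   "z_triglycerides", "z_sbp"]]
        cov = df[["subject_id", "sex", "age_years", "race_ethnicity",
                  "puberty_score", "maternal_college", "prepreg_bmi",
                  "smoking"]]
        table, carried = run_step1(mil, mets, cov)
        assert len(table) == 16  # 4 exposures x 2 sexes x 2 tiers
        assert set(table.tier) == {"unadjusted", "M1"}
        assert set(carried) == {"male", "female"}

    def test_planted_path_carried_through(self):
        rng = np.random.default_rng(2024)
        df = make_screen_data(rng, n=400, beta_a=0.5, beta_b=0.6)
        mil = df[["subject_id", "sex", "age_peak", "bmi_peak", "age_rebound",
                  "bmi_rebound"]]
        mets = df[["subject_id", "mets_z", "z_waist", "z_homa_ir", "z_hdl",
                   "z_triglycerides", "z_sbp"]]
        cov = df[["subject_id", "sex", "age_years", "race_ethnicity",
                  "puberty_score", "maternal_college", "prepreg_bmi",
                  "smoking"]]
        eig = {sex: df.loc[df.sex == sex, ["subject_id", "ME1", "ME2"]]
               .set_index("subject_id") for sex in ("male", "female")}
        results = run_screen(mil, eig, mets, cov)
        assert "age_rebound" in results["carried_milestones"]["male"]
        assert ("age_rebound", "ME1") in results["carried_pairs"]["male"]
        step3 = results["step3"]
        me1_m1 = step3[(step3.exposure == "ME1") & (step3.tier == "M1")
                       & (step3.stratum == "male")]
        assert me1_m1.nominal_flag.all()
        # component follow-up only for M1-significant MEs, 5 components each
        comp = results["components"]
        assert set(comp[comp.stratum == "male"].outcome) == {
            "z_waist", "z_homa_ir", "z_hdl", "z_triglycerides", "z_sbp"}
        assert (comp.tier == "M1").all()

    def test_step2_fdr_family_per_sex(self, rng):
        df = make_screen_data(rng, n=300)
        mil = df[["subject_id", "sex", "age_peak", "bmi_peak", "age_rebound",
                  "bmi_rebound"]]
        cov = df[["subject_id", "sex", "age_years", "race_ethnicity"]]
        eig = {sex: df.loc[df.sex == sex, ["subject_id", "ME1", "ME2"]]
               .set_index("subject_id") for sex in ("male", "female")}
        carried = {"male": ["age_rebound", "bmi_rebound"], "female": []}
        table, pairs = run_step2(carried, mil, eig, cov)
        assert set(table.stratum) == {"male"}
        assert len(table) == 4  # 2 milestones x 2 MEs
        # flags equal BH applied to the male family jointly
        np.testing.assert_array_equal(
            table.fdr_flag.to_numpy(), bh_fdr(table.p.to_numpy(), 0.05))
        assert pairs["female"] == []

    def test_step3_empty_carried_gives_empty_tables(self, rng):
        df = make_screen_data(rng)
        mets = df[["subject_id", "mets_z", "z_waist", "z_homa_ir", "z_hdl",
                   "z_triglycerides", "z_sbp"]]
        cov = df[["subject_id", "sex", "age_years", "race_ethnicity",
                  "puberty_score", "maternal_college", "prepreg_bmi",
                  "smoking"]]
        mil = df[["subject_id", "sex", "age_peak", "bmi_peak", "age_rebound",
                  "bmi_rebound"]]
        eig = {sex: df.loc[df.sex == sex, ["subject_id", "ME1", "ME2"]]
               .set_index("subject_id") for sex in ("male", "female")}
        table, comp = run_step3({"male": [], "female": []}, eig, mets, cov,
                                mil)
        assert table.empty and comp.empty


class TestSensitivity:
    def _tables(self, df):
        mil = df[["subject_id", "sex", "age_peak", "bmi_peak", "age_rebound",
                  "bmi_rebound"]]
        cov = df[["subject_id", "sex", "age_years", "race_ethnicity"]]
        eig = {sex: df.loc[df.sex == sex, ["subject_id", "ME1", "ME2"]]
               .set_index("subject_id") for sex in ("male", "female")}
        return mil, cov, eig

    def test_independent_exposures_change_little(self):
        rng = np.random.default_rng(5)
        df = make_screen_data(rng, n=1000, beta_a=0.5)
        mil, cov, eig = self._tables(df)
        step2, _ = run_step2({"male": ["age_rebound"], "female": []},
                             mil, eig, cov)
        sens = sensitivity_mutual_adjustment(step2, mil, eig, cov)
        planted = sens[(sens.exposure == "age_rebound")
                       & (sens.outcome == "ME1")].iloc[0]
        assert abs(planted["pct_change"]) < 10.0
        assert {"beta_unadjusted_for_sibling", "beta_adjusted",
                "sibling"} <= set(sens.columns)

    def test_collinear_siblings_raise(self, rng):
        df = make_screen_data(rng, n=200, beta_a=0.4)
        df["bmi_rebound"] = 3.0 * df["age_rebound"]  # deterministic sibling
        mil, cov, eig = self._tables(df)
        step2, _ = run_step2({"male": ["age_rebound"], "female": []},
                             mil, eig, cov)
        with pytest.raises(ValueError, match="collinear"):
            sensitivity_mutual_adjustment(step2, mil, eig, cov)


class TestNullBehaviour:
    def test_type_one_error_near_alpha(self):
        rejections = 0
        reps = 300
        for rep in range(reps):
            r = np.random.default_rng(10_000 + rep)
            df = pd.DataFrame({"x": r.normal(size=150),
                               "y": r.normal(size=150)})
            res = fit_linear_association(df, "y", "x")
            rejections += res.p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.035  # ~3 MC sd

    def test_null_screen_carries_little(self):
        empty = 0
        reps = 30
        for rep in range(reps):
            r = np.random.default_rng(20_000 + rep)
            df = make_screen_data(r, n=200)
            mil = df[["subject_id", "sex", "age_peak", "bmi_peak",
                      "age_rebound", "bmi_rebound"]]
            cov = df[["subject_id", "sex", "age_years", "race_ethnicity"]]
            eig = {s: df.loc[df.sex == s, ["subject_id", "ME1", "ME2"]]
                   .set_index("subject_id") for s in ("male", "female")}
            carried = {"male": list(), "female": list()}
            # carry everything to step 2 to exercise the null FDR family
            carried = {"male": ["age_peak", "age_rebound"],
                       "female": ["age_peak", "age_rebound"]}
            _, pairs = run_step2(carried, mil, eig, cov)
            empty += (len(pairs["male"]) + len(pairs["female"])) == 0
        assert empty / reps >= 0.8
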