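"""Network construction: correlations, adjacency, TOM, consensus, dynamic
tree cut, eigengenes, kME, and the outlier-sample screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from milemet import (ConsensusNetwork, NetworkConfig, SimulationConfig,
                     consensus_tom, detect_modules, detect_outlier_samples,
                     eigengene_scores, membership_report, signed_adjacency,
                     simulate_cohort, spearman_correlation,
                     topological_overlap)
from milemet.network import module_eigengene, tom_dissimilarity


def tom_brute_force(a):
    """Triple-loop TOM oracle (independent of the matrix-product path)."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    omega = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            omega[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return omega


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def planted_block_data(rng, n_samples, block_sizes, rho_within,
                       n_background=0):
    """Columns with exchangeable within-block correlation rho_within."""
    loading = np.sqrt(rho_within)
    cols, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            cols.append(loading * f + np.sqrt(1 - rho_within)
                        * rng.standard_normal(n_samples))
            labels.append(b)
    for _ in range(n_background):
        cols.append(rng.standard_normal(n_samples))
        labels.append(0)
    return np.column_stack(cols), np.array(labels)


def tom_d_from_data(X, beta=10.0):
    rho = spearman_correlation(X)
    return tom_dissimilarity(topological_overlap(signed_adjacency(rho, beta)))


class TestSpearman:
    def test_monotone_and_reversed_pairs(self):
        x = np.arange(10.0)
        X = np.column_stack([x, np.exp(x), -x])
        rho = spearman_correlation(X)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_ties_match_scipy_oracle(self, rng):
        X = rng.integers(0, 4, size=(20, 5)).astype(float)  # heavy ties
        X += rng.normal(0, 1e-9, size=X.shape)  # avoid constant columns
        rho = spearman_correlation(X)
        expected = spearmanr(X).statistic
        np.testing.assert_allclose(rho, expected, atol=1e-6)

    def test_constant_column_raises(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(X)


class TestAdjacencyAndTOM:
    def test_signed_adjacency_closed_forms(self):
        rho = np.array([[1.0, -1.0, 0.0],
                        [-1.0, 1.0, 1.0],
                        [0.0, 1.0, 1.0]])
        a = signed_adjacency(rho, beta=10)
        assert a[0, 1] == pytest.approx(0.0)
        assert a[1, 2] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(2.0 ** -10)

    def test_tom_two_nodes_closed_form(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        omega = topological_overlap(a)
        assert omega[0, 1] == pytest.approx(0.3)

    def test_tom_three_nodes_all_half(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        omega = topological_overlap(a)
        off = omega[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_tom_matches_brute_force(self, rng):
        for n in (5, 17, 30):
            a = random_adjacency(rng, n)
            fast = topological_overlap(a)
            slow = tom_brute_force(a)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_tom_symmetric_unit_interval(self, rng):
        a = random_adjacency(rng, 25)
        omega = topological_overlap(a)
        assert np.allclose(omega, omega.T)
        assert omega.min() >= 0 and omega.max() <= 1 + 1e-12
        d = tom_dissimilarity(omega)
        assert np.allclose(np.diag(d), 0.0)


class TestConsensus:
    def test_identical_strata_idempotent(self, rng):
        a = random_adjacency(rng, 20)
        omega = topological_overlap(a)
        cons = consensus_tom({"m": omega, "f": omega},
                             calibration_quantile=None)
        np.testing.assert_allclose(cons, omega)

    def test_min_rule_without_calibration(self):
        t1 = np.array([[1.0, 0.3], [0.3, 1.0]])
        t2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        cons = consensus_tom({"m": t1, "f": t2}, calibration_quantile=None)
        assert cons[0, 1] == pytest.approx(0.3)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            consensus_tom({"m": np.eye(3), "f": np.eye(4)})

    def test_calibration_matches_quantiles(self, rng):
        t1 = topological_overlap(random_adjacency(rng, 30))
        t2 = topological_overlap(random_adjacency(rng, 30)) * 0.5
        np.fill_diagonal(t2, 1.0)
        cons = consensus_tom({"m": t1, "f": t2}, calibration_quantile=0.95)
        assert cons.max() <= 1.0 and np.allclose(np.diag(cons), 1.0)


class TestDetectModules:
    def test_planted_blocks_recovered(self, rng):
        X, labels = planted_block_data(rng, 200, [30] * 5, rho_within=0.7)
        found = detect_modules(tom_d_from_data(X))
        assert adjusted_rand_score(labels, found) >= 0.9

    def test_pure_noise_mostly_unassigned(self):
        unassigned = []
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            X = r.standard_normal((80, 100))
            found = detect_modules(tom_d_from_data(X))
            unassigned.append((found == 0).mean())
        assert np.mean(unassigned) >= 0.8

    def test_small_block_forced_to_zero(self, rng):
        X, labels = planted_block_data(rng, 200, [10], rho_within=0.8,
                                       n_background=40)
        found = detect_modules(tom_d_from_data(X),
                               NetworkConfig(min_module_size=20))
        assert (found[labels == 1] == 0).all()

    def test_permutation_equivariance(self, rng):
        X, _ = planted_block_data(rng, 150, [25, 25], rho_within=0.7,
                                  n_background=30)
        d = tom_d_from_data(X)
        labels = detect_modules(d)
        perm = rng.permutation(d.shape[0])
        labels_perm = detect_modules(d[np.ix_(perm, perm)])
        assert adjusted_rand_score(labels[perm], labels_perm) == pytest.approx(1.0)

    def test_recovery_degrades_with_loading(self):
        r = np.random.default_rng(77)
        aris = []
        for rho_w in (0.8, 0.6, 0.4):
            X, labels = planted_block_data(r, 200, [30] * 3, rho_within=rho_w,
                                           n_background=30)
            found = detect_modules(tom_d_from_data(X))
            aris.append(adjusted_rand_score(labels, found))
        assert aris[0] >= aris[1] >= aris[2] or (
            aris[0] >= 0.9 and aris[1] >= 0.9 and aris[2] <= aris[1] + 0.05)

    def test_fewer_metabolites_than_min_size(self):
        d = np.zeros((5, 5))
        assert (detect_modules(d, NetworkConfig(min_module_size=20)) == 0).all()


class TestEigengenes:
    def test_rank_one_module_exact(self):
        x = np.arange(20.0)
        sub = np.column_stack([x, x])
        score, ve = module_eigengene(sub)
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(score, x)[0, 1] == pytest.approx(1.0)
        assert score.std(ddof=1) == pytest.approx(1.0)

    def test_recovers_planted_factor(self, rng):
        f = rng.standard_normal(500)
        members = np.column_stack(
            [0.8 * f + 0.6 * rng.standard_normal(500) for _ in range(25)])
        score, ve = module_eigengene(members)
        assert abs(np.corrcoef(score, f)[0, 1]) >= 0.95

    def test_matches_power_iteration_oracle(self, rng):
        X = rng.standard_normal((100, 12))
        score, _ = module_eigengene(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        v = np.ones(12)
        C = Xs.T @ Xs
        for _ in range(2000):
            v = C @ v
            v /= np.linalg.norm(v)
        oracle = Xs @ v
        assert abs(np.corrcoef(score, oracle)[0, 1]) > 1 - 1e-8

    def test_sign_oriented_positive_mean_kme(self, rng):
        f = rng.standard_normal(300)
        members = np.column_stack(
            [0.9 * f + 0.44 * rng.standard_normal(300) for _ in range(10)])
        score, _ = module_eigengene(members)
        kme = [np.corrcoef(members[:, j], score)[0, 1] for j in range(10)]
        assert np.mean(kme) > 0

    def test_eigengene_scores_kme_member_of_rank1(self, rng):
        x = rng.standard_normal(50)
        mat = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)})
        labels = np.array([1, 1, 0])
        es = eigengene_scores({"all": mat}, labels)
        assert es.kme["all"].loc["a", "ME1"] == pytest.approx(1.0)
        assert es.variance_explained["all"][1] == pytest.approx(1.0)


class TestMembershipReport:
    def test_threshold_and_ranking(self, rng):
        loadings = np.linspace(0.95, 0.55, 25)
        f = rng.standard_normal(500)
        members = np.column_stack([lam * f + np.sqrt(1 - lam ** 2)
                                   * rng.standard_normal(500)
                                   for lam in loadings])
        mat = pd.DataFrame(members,
                           columns=[f"M{i:02d}" for i in range(25)])
        labels = np.ones(25, dtype=int)
        es = eigengene_scores({"all": mat}, labels)
        rep = membership_report(es, labels, threshold=0.6)
        top10 = rep[rep.top10].sort_values("rank")
        assert len(top10) == 10
        # planted loadings strictly ordered -> kME ranking matches
        assert list(top10.metabolite_id) == [f"M{i:02d}" for i in range(10)]
        assert (rep.kme.abs() > 0.6).all() or (rep.top10).any()


class TestOutlierDetection:
    def test_null_rarely_flags(self):
        n_flagged = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            mat = pd.DataFrame(r.standard_normal((60, 40)))
            n_flagged += len(detect_outlier_samples(mat, -2.5))
        assert n_flagged / (50 * 60) < 0.02

    def test_spiked_sample_flagged(self):
        # realistic structured metabolome; permuting one sample's profile
        # destroys its participation in the shared correlation structure
        from milemet import MetabolitePreprocessor
        ds = simulate_cohort(SimulationConfig(n_reference=2000), seed=3)
        proc = MetabolitePreprocessor().fit_transform(
            ds.metabolites, ds.metabolite_meta)
        X = proc.copy()
        X.iloc[5] = np.random.default_rng(0).permutation(
            X.iloc[5].to_numpy())
        flagged = detect_outlier_samples(X, -2.5)
        assert X.index[5] in list(flagged)

    def test_minus_infinity_threshold_flags_nothing(self, rng):
        mat = pd.DataFrame(rng.standard_normal((30, 20)))
        assert len(detect_outlier_samples(mat, -np.inf)) == 0

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError):
            detect_outlier_samples(pd.DataFrame(rng.standard_normal((5, 10))))


class TestConsensusNetworkEstimator:
    def test_consensus_equals_single_stratum_when_identical(self, rng):
        X, labels = planted_block_data(rng, 150, [25, 25], rho_within=0.7,
                                       n_background=20)
        d = tom_d_from_data(X)
        single = detect_modules(d, NetworkConfig())
        tom = 1.0 - d
        np.fill_diagonal(tom, 1.0)
        cons = consensus_tom({"m": tom, "f": tom}, calibration_quantile=None)
        both = detect_modules(tom_dissimilarity(cons), NetworkConfig())
        np.testing.assert_array_equal(single, both)

    def test_fit_on_synthetic_cohort(self, small_cohort):
        from milemet import MetabolitePreprocessor
        processed = MetabolitePreprocessor().fit_transform(
            small_cohort.metabolites, small_cohort.metabolite_meta)
        strata = small_cohort.covariates.set_index("subject_id")["sex"]
        net = ConsensusNetwork().fit(processed, strata)
        assert net.labels_.shape[0] == processed.shape[1]
        assert set(net.eigengenes_.eigengenes) == {"female", "male"}
        for eig in net.eigengenes_.eigengenes.values():
            assert (eig.std(ddof=1) - 1.0).abs().max() < 1e-8
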