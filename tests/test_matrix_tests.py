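"""Distance construction and matrix association tests, cross-checked against
exhaustive enumeration and scikit-bio's Mantel implementation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from scutpop.core_data import DistanceMatrix, SiteTable, ValidationError
from scutpop.matrix_tests import (
    environmental_distance,
    geographic_distance,
    mantel,
    mmrr,
    partial_mantel,
)


def rand_dm(n, rng, labels=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels or [f"p{i}" for i in range(n)], m)


class TestGeographicDistance:
    def test_identical_coordinates_zero(self):
        s = SiteTable("a", 25.0, 121.5, 10)
        t = SiteTable("b", 25.0, 121.5, 10)
        assert geographic_distance([s, t]).values[0, 1] == 0.0

    def test_pure_altitude_km(self):
        s = SiteTable("a", 25.0, 121.5, 0)
        t = SiteTable("b", 25.0, 121.5, 1000)
        assert geographic_distance([s, t]).values[0, 1] == pytest.approx(1.0)

    def test_projected_matches_haversine_oracle(self, taiwan_sites):
        geo = geographic_distance(taiwan_sites)
        by = {s.population: s for s in taiwan_sites}
        R = 6371.0088
        for a, b in [("YH", "DA"), ("YH", "XH"), ("MK", "EG")]:
            sa, sb = by[a], by[b]
            p1, p2 = math.radians(sa.latitude), math.radians(sb.latitude)
            dphi, dl = p2 - p1, math.radians(sb.longitude - sa.longitude)
            h = (math.sin(dphi / 2) ** 2
                 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2)
            hav = 2 * R * math.asin(math.sqrt(h))
            oracle = math.sqrt(hav**2 + ((sb.altitude - sa.altitude) / 1000) ** 2)
            got = geo.values[geo.labels.index(a), geo.labels.index(b)]
            assert got == pytest.approx(oracle, rel=0.01)

    def test_raw_mode_mixes_units(self):
        s = SiteTable("a", 25.0, 121.5, 0)
        t = SiteTable("b", 25.0, 121.5, 100)
        assert geographic_distance([s, t], mode="raw").values[0, 1] == 100.0


class TestEnvironmentalDistance:
    def test_identical_rows_zero(self, taiwan_sites):
        env = environmental_distance(taiwan_sites)
        assert np.diag(env.values).max() == 0.0

    def test_single_variable_delta_unstandardized(self):
        s = SiteTable("a", 0, 0, 0, {"bio2": 5.0})
        t = SiteTable("b", 0, 0, 0, {"bio2": 7.5})
        d = environmental_distance([s, t], ("bio2",), standardize=False)
        assert d.values[0, 1] == pytest.approx(2.5)

    def test_full_matrix_matches_brute_force(self, taiwan_sites):
        from scutpop.core_data import BIOCLIM_VARS
        env = environmental_distance(taiwan_sites, standardize=False)
        X = np.array([[s.climate[v] for v in BIOCLIM_VARS] for s in taiwan_sites])
        for i in range(9):
            for j in range(9):
                assert env.values[i, j] == pytest.approx(
                    math.dist(X[i], X[j]))

    def test_missing_variable_is_schema_error(self):
        s = SiteTable("a", 0, 0, 0, {"bio2": 5.0})
        with pytest.raises(ValidationError):
            environmental_distance([s, s], ("bio2", "bio8"))


class TestMantel:
    def test_monotone_transform_rho_one(self):
        rng = np.random.default_rng(0)
        A = rand_dm(6, rng)
        B = DistanceMatrix(A.labels, A.values**2)
        assert mantel(A, B, perms=99, seed=1).coefficients["rho"] == pytest.approx(1.0)

    def test_rank_reversal_rho_minus_one(self):
        rng = np.random.default_rng(1)
        A = rand_dm(6, rng)
        B = DistanceMatrix(A.labels, 1.0 / (A.values + 1.0)
                           - np.eye(6) / (0 + 1.0))
        assert mantel(A, B, perms=99, seed=1).coefficients["rho"] == pytest.approx(-1.0)

    def test_exhaustive_permutation_oracle_4x4(self):
        rng = np.random.default_rng(2)
        A, B = rand_dm(4, rng), rand_dm(4, rng)
        iu = np.triu_indices(4, 1)
        rho_obs = stats.spearmanr(A.values[iu], B.values[iu]).statistic
        hits = sum(
            stats.spearmanr(A.values[iu],
                            B.values[np.ix_(p, p)][iu]).statistic >= rho_obs
            for p in itertools.permutations(range(4)))
        exact = hits / math.factorial(4)
        est = mantel(A, B, perms=49999, seed=3).p_values["rho"]
        assert est == pytest.approx(exact, abs=0.01)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        A, B = rand_dm(9, rng), rand_dm(9, rng)
        r_skb, p_skb, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(A.values, A.labels),
            skbio.DistanceMatrix(B.values, B.labels),
            method="spearman", permutations=9999, alternative="greater")
        mine = mantel(A, B, perms=9999, seed=5)
        assert mine.coefficients["rho"] == pytest.approx(r_skb, abs=1e-12)
        assert mine.p_values["rho"] == pytest.approx(p_skb, abs=0.03)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        A, B = rand_dm(7, rng), rand_dm(7, rng)
        perm = rng.permutation(7)
        Ap = DistanceMatrix([A.labels[i] for i in perm],
                            A.values[np.ix_(perm, perm)])
        Bp = DistanceMatrix([B.labels[i] for i in perm],
                            B.values[np.ix_(perm, perm)])
        r1 = mantel(A, B, perms=99, seed=7).coefficients["rho"]
        r2 = mantel(Ap, Bp, perms=99, seed=7).coefficients["rho"]
        assert r1 == pytest.approx(r2)

    def test_constant_matrix_rejected(self):
        A = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        rng = np.random.default_rng(8)
        with pytest.raises(ValidationError):
            mantel(A, rand_dm(3, rng, list("abc")), perms=9, seed=0)

    def test_null_p_roughly_uniform(self):
        # p-values of independent random pairs spread over (0, 1]
        rng = np.random.default_rng(9)
        ps = [mantel(rand_dm(9, rng), rand_dm(9, rng),
                     perms=99, seed=k).p_values["rho"] for k in range(200)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestPartialMantel:
    def test_b_equals_a_partial_one(self):
        rng = np.random.default_rng(10)
        A = rand_dm(7, rng)
        C = rand_dm(7, rng, A.labels)
        res = partial_mantel(A, A, C, perms=99, seed=0)
        assert res.coefficients["rho"] == pytest.approx(1.0)

    def test_uncorrelated_conditioner_preserves_simple_rho(self):
        rng = np.random.default_rng(11)
        diffs = []
        for k in range(20):
            A, B, C = (rand_dm(9, rng) for _ in range(3))
            B = DistanceMatrix(A.labels, B.values)
            C = DistanceMatrix(A.labels, C.values)
            simple = mantel(A, B, perms=9, seed=k).coefficients["rho"]
            partial = partial_mantel(A, B, C, perms=9, seed=k).coefficients["rho"]
            diffs.append(partial - simple)
        assert abs(np.mean(diffs)) < 0.05

    def test_b_explained_by_c_partial_near_zero(self):
        rng = np.random.default_rng(12)
        C = rand_dm(9, rng)
        noise = rand_dm(9, rng, C.labels).values
        B = DistanceMatrix(C.labels, 2.0 * C.values + 0.3 * noise)
        A = DistanceMatrix(C.labels,
                           C.values + 0.3 * rand_dm(9, rng, C.labels).values)
        res = partial_mantel(A, B, C, perms=99, seed=1)
        assert abs(res.coefficients["rho"]) < 0.2


class TestMmrr:
    def test_exact_linear_combination_r2_one(self):
        rng = np.random.default_rng(13)
        X1, X2 = rand_dm(8, rng), rand_dm(8, rng)
        X2 = DistanceMatrix(X1.labels, X2.values)
        Y = DistanceMatrix(X1.labels, 2 * X1.values + 3 * X2.values)
        res = mmrr(Y, {"x1": X1, "x2": X2}, perms=49, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_single_predictor_beta_equals_pearson_mantel(self):
        rng = np.random.default_rng(14)
        A, B = rand_dm(9, rng), rand_dm(9, rng)
        B = DistanceMatrix(A.labels, B.values)
        res = mmrr(A, {"x": B}, perms=9, seed=0)
        iu = np.triu_indices(9, 1)
        r = stats.pearsonr(A.values[iu], B.values[iu]).statistic
        assert abs(res.coefficients["x"] - r) < 1e-10

    def test_independent_matrices_mean_beta_near_zero(self):
        rng = np.random.default_rng(15)
        betas = []
        for k in range(200):
            A, B = rand_dm(9, rng), rand_dm(9, rng)
            B = DistanceMatrix(A.labels, B.values)
            betas.append(mmrr(A, {"x": B}, perms=0, seed=0).coefficients["x"])
        assert abs(np.mean(betas)) < 0.03

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(16)
        X = rand_dm(6, rng)
        X2 = DistanceMatrix(X.labels, 2 * X.values)
        Y = rand_dm(6, rng, X.labels)
        with pytest.raises(ValidationError):
            mmrr(Y, {"a": X, "b": X2}, perms=9, seed=0)
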