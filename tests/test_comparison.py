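"""Matrix correlations (random skewers, Mantel, Krzanowski, PCA similarity)
and matrix distances (overlap, Riemannian)."""

import numpy as np
import pytest
from scipy import integrate, stats

from quantmat import (
    TraitMatrix,
    compare_all,
    corrected_correlation,
    krz_cor,
    mantel_cor,
    matrix_distance,
    overlap_q,
    pca_similarity,
    random_skewers,
    random_unit_vectors,
    to_correlation,
)
from quantmat.core import ValidationError


class TestRandomSkewers:
    def test_self_comparison_exactly_one(self, spd_factory):
        m = spd_factory(5, 1)
        assert random_skewers(m, m, 200, rng=0).value == 1.0

    def test_matches_bruteforce_mc_oracle(self):
        a = TraitMatrix(np.diag([10.0, 1.0]), ["x", "y"], "covariance")
        b = TraitMatrix(np.diag([1.0, 10.0]), ["x", "y"], "covariance")
        got = random_skewers(a, b, 100_000, rng=3).value
        # independent brute-force loop with its own draws
        g = np.random.default_rng(999)
        acc = 0.0
        n = 100_000
        betas = g.standard_normal((n, 2))
        betas /= np.linalg.norm(betas, axis=1, keepdims=True)
        for i in range(0, n, 10_000):
            chunk = betas[i:i + 10_000]
            ra, rb = chunk @ a.values, chunk @ b.values
            acc += np.sum(np.einsum("ij,ij->i", ra, rb)
                          / (np.linalg.norm(ra, axis=1)
                             * np.linalg.norm(rb, axis=1)))
        assert abs(got - acc / n) < 0.01

    def test_symmetric_under_shared_skewers(self, spd_factory):
        a, b = spd_factory(4, 5), spd_factory(4, 6)
        betas = random_unit_vectors(4, 500, 7)
        assert (random_skewers(a, b, betas=betas).value
                == random_skewers(b, a, betas=betas).value)

    def test_scale_invariant(self, spd_factory):
        a, b = spd_factory(4, 8), spd_factory(4, 9)
        betas = random_unit_vectors(4, 300, 10)
        v1 = random_skewers(a, b, betas=betas).value
        v2 = random_skewers(a.with_values(7.3 * a.values), b, betas=betas).value
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_dimension_mismatch_rejected(self, spd_factory):
        with pytest.raises(ValidationError):
            random_skewers(spd_factory(3, 0), spd_factory(4, 1))


class TestMantel:
    def test_self_comparison(self, corr_factory):
        m = corr_factory(5, 2)
        res = mantel_cor(m, m, permutations=99, rng=0)
        assert res.value == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_antisymmetry(self, corr_factory):
        a = corr_factory(4, 3)
        neg = a.values.copy() * -1
        np.fill_diagonal(neg, 1.0)
        b = TraitMatrix(neg, a.labels, "correlation")
        assert mantel_cor(a, b, permutations=49, rng=1).value == pytest.approx(-1.0)

    def test_equals_direct_pearson_of_elements(self, corr_factory):
        a, b = corr_factory(4, 4), corr_factory(4, 5)
        il = np.tril_indices(4, k=-1)
        expected = stats.pearsonr(a.values[il], b.values[il]).statistic
        assert mantel_cor(a, b, permutations=49, rng=2).value == pytest.approx(expected)

    def test_covariance_rejected(self, spd_factory):
        with pytest.raises(ValidationError):
            mantel_cor(spd_factory(4, 6), spd_factory(4, 7))

    def test_null_p_values_uniform(self, corr_factory):
        # comparing a matrix against its own random relabelings: the observed
        # statistic is itself a draw from the permutation null, so p is uniform
        a = corr_factory(6, 8)
        g = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            perm = g.permutation(6)
            b = TraitMatrix(a.values[np.ix_(perm, perm)],
                            a.labels, "correlation")
            ps.append(mantel_cor(a, b, permutations=99, rng=g).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestKrzanowski:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_self_comparison_is_one(self, k, spd_factory):
        m = spd_factory(8, 10)
        assert krz_cor(m, m, k=k).value == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_subspaces_zero(self):
        labels = list("wxyz")
        a = TraitMatrix(np.diag([8.0, 4.0, 1e-3, 1e-3]), labels, "covariance")
        b = TraitMatrix(np.diag([1e-3, 1e-3, 8.0, 4.0]), labels, "covariance")
        assert krz_cor(a, b, k=1).value == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self, spd_factory):
        a, b = spd_factory(6, 11), spd_factory(6, 12)
        r = stats.ortho_group.rvs(6, random_state=np.random.default_rng(13))
        ra = a.with_values(r @ a.values @ r.T)
        rb = b.with_values(r @ b.values @ r.T)
        assert krz_cor(ra, rb).value == pytest.approx(krz_cor(a, b).value,
                                                      abs=1e-10)

    def test_default_k(self, spd_factory):
        assert krz_cor(spd_factory(8, 14), spd_factory(8, 15)).extra["k"] == 3
        assert krz_cor(spd_factory(3, 16), spd_factory(3, 17)).extra["k"] == 1

    def test_bad_k_rejected(self, spd_factory):
        with pytest.raises(ValidationError):
            krz_cor(spd_factory(4, 18), spd_factory(4, 19), k=4)


class TestPCASimilarity:
    def test_self_comparison_is_one(self, spd_factory):
        m = spd_factory(7, 20)
        assert pca_similarity(m, m).value == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_variation_near_zero(self):
        a = TraitMatrix(np.diag([1.0, 1e-6]), ["x", "y"], "covariance")
        b = TraitMatrix(np.diag([1e-6, 1.0]), ["x", "y"], "covariance")
        assert pca_similarity(a, b).value <= 1e-5

    def test_equals_double_loop(self, spd_factory):
        from quantmat import eigen

        a, b = spd_factory(5, 21), spd_factory(5, 22)
        wa, va = eigen(a)
        wb, vb = eigen(b)
        num = sum(wa[i] * wb[j] * (va[:, i] @ vb[:, j]) ** 2
                  for i in range(5) for j in range(5))
        den = sum(wa[i] * wb[i] for i in range(5))
        assert pca_similarity(a, b).value == pytest.approx(num / den, abs=1e-12)


class TestMatrixDistance:
    def test_riemann_diag_closed_form(self):
        a = TraitMatrix(np.diag([np.e**2, 1.0]), ["x", "y"], "covariance")
        b = TraitMatrix(np.eye(2), ["x", "y"], "covariance")
        assert matrix_distance(a, b, "riemann").value == pytest.approx(2.0,
                                                                       abs=1e-12)

    def test_riemann_congruence_invariance(self, spd_factory, rng):
        a, b = spd_factory(5, 23), spd_factory(5, 24)
        t = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        ta = a.with_values(t @ a.values @ t.T)
        tb = b.with_values(t @ b.values @ t.T)
        d1 = matrix_distance(a, b, "riemann").value
        d2 = matrix_distance(ta, tb, "riemann").value
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_riemann_symmetry_and_inversion(self, spd_factory):
        a, b = spd_factory(4, 25), spd_factory(4, 26)
        d = matrix_distance(a, b, "riemann").value
        assert matrix_distance(b, a, "riemann").value == pytest.approx(d, abs=1e-8)
        ai = a.with_values(np.linalg.inv(a.values))
        bi = b.with_values(np.linalg.inv(b.values))
        assert matrix_distance(ai, bi, "riemann").value == pytest.approx(d, abs=1e-8)

    def test_overlap_self_is_half(self, spd_factory):
        m = spd_factory(3, 27)
        res = matrix_distance(m, m, "overlap", mc_draws=10_000, rng=28)
        se = 0.5 / np.sqrt(10_000)  # ratio variance is bounded by 1/4
        assert abs(res.extra["q"] - 0.5) <= 3 * se
        assert res.value <= 0.1

    def test_overlap_triangle_inequality(self, spd_factory):
        a, b, c = (spd_factory(3, s) for s in (29, 30, 31))
        d = lambda x, y: matrix_distance(x, y, "overlap", mc_draws=4000,
                                         rng=32).value
        assert d(a, c) <= d(a, b) + d(b, c) + 0.05

    def test_overlap_1d_matches_quadrature(self):
        s1, s2 = 1.0, 2.5
        f = stats.norm(0, s1).pdf
        g = stats.norm(0, s2).pdf
        q_fg = integrate.quad(lambda x: g(x) * f(x) / (f(x) + g(x)),
                              -40, 40)[0]
        q_gf = integrate.quad(lambda x: f(x) * g(x) / (f(x) + g(x)),
                              -40, 40)[0]
        expected = (q_fg + q_gf) / 2
        got = overlap_q(np.array([[s1**2]]), np.array([[s2**2]]),
                        mc_draws=100_000, rng=33)
        assert abs(got - expected) < 0.005

    def test_non_pd_rejected(self):
        a = TraitMatrix(np.diag([1.0, 0.0]), ["x", "y"], "covariance")
        b = TraitMatrix(np.eye(2), ["x", "y"], "covariance")
        with pytest.raises(ValidationError):
            matrix_distance(a, b, "riemann")


class TestCorrectionAndDriver:
    def test_corrected_identity_when_reps_one(self):
        assert corrected_correlation(0.8, 1.0, 1.0) == pytest.approx(0.8)

    def test_corrected_capped_at_one(self):
        assert corrected_correlation(0.5, 0.64, 0.25) == 1.0

    def test_corrected_arithmetic(self):
        assert corrected_correlation(0.6, 0.9, 0.9) == pytest.approx(0.6 / 0.9)

    def test_zero_repeatability_rejected(self):
        with pytest.raises(ValidationError):
            corrected_correlation(0.5, 0.0, 1.0)

    def test_compare_all_layout(self, spd_factory):
        a = spd_factory(4, 34)
        table = compare_all([a, a, a], method="pca_similarity",
                            repeatabilities=[1.0, 1.0, 1.0])
        off = table.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-10)
        np.testing.assert_allclose(np.diag(table), 1.0)

    def test_compare_all_corrected_triangle(self, spd_factory):
        mats = [spd_factory(4, s) for s in (35, 36)]
        table = compare_all(mats, method="pca_similarity",
                            repeatabilities=[0.8, 0.8])
        raw = table.iloc[1, 0]
        assert table.iloc[0, 1] == pytest.approx(min(raw / 0.8, 1.0))
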