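"""Bootstrap/Monte-Carlo machinery, matrix repeatabilities, rarefaction,
eigenvalue extension."""

import numpy as np
import pytest

from quantmat import (
    TraitMatrix,
    alpha_rep,
    bootstrap_rep,
    bootstrap_stat,
    extend_matrix,
    monte_carlo_rep,
    monte_carlo_stat,
    rarefaction,
    simulate_population,
)
from quantmat.core import ValidationError
from quantmat.resampling import suggest_extension_rank
from quantmat.synthetic import random_spd


class TestGenericResampling:
    def test_bootstrap_constant_statistic(self):
        pop = simulate_population(random_spd(3, 0), 20, rng=1)
        pop.data["t1"] = 4.0
        draws = bootstrap_stat(pop, lambda d: d.traits()[:, 0].mean(),
                               iterations=25, rng=2)
        assert all(v == 4.0 for v in draws)

    def test_bootstrap_mean_covariance_near_truth(self):
        truth = random_spd(3, 3)
        pop = simulate_population(truth, 500, rng=4)
        draws = bootstrap_stat(
            pop, lambda d: np.cov(d.traits(), rowvar=False),
            iterations=50, rng=5)
        mean = np.mean(draws, axis=0)
        assert (np.linalg.norm(mean - truth.values)
                <= 0.1 * np.linalg.norm(truth.values))

    def test_bootstrap_seeding(self):
        pop = simulate_population(random_spd(3, 6), 30, rng=7)
        stat = lambda d: d.traits().sum()
        a = bootstrap_stat(pop, stat, iterations=10, rng=8)
        b = bootstrap_stat(pop, stat, iterations=10, rng=8)
        assert a == b

    def test_monte_carlo_lln(self):
        m = random_spd(3, 9)
        draws = monte_carlo_stat(m, 20_000,
                                 lambda x: np.cov(x, rowvar=False),
                                 iterations=3, rng=10)
        for d in draws:
            assert np.linalg.norm(d - m.values) <= 0.05 * np.linalg.norm(m.values)

    def test_monte_carlo_rejects_non_pd(self):
        m = TraitMatrix(np.diag([1.0, 0.0]), ["a", "b"], "covariance")
        with pytest.raises(ValidationError):
            monte_carlo_stat(m, 10, lambda x: 0.0, iterations=1, rng=0)


class TestMatrixRepeatabilities:
    def test_bootstrap_rep_large_sample_high(self):
        pop = simulate_population(random_spd(4, 11,
                                             eigenvalues=np.array([8, 4, 2, 1.0])),
                                  1000, rng=12)
        est = bootstrap_rep(pop, "random_skewers", iterations=30, rng=13)
        assert est.value >= 0.95

    def test_bootstrap_rep_small_sample_lower(self):
        truth = random_spd(10, 14)
        big = simulate_population(truth, 1000, rng=15)
        small = simulate_population(truth, 12, rng=16)
        hi = bootstrap_rep(big, "pca_similarity", iterations=25, rng=17).value
        lo = bootstrap_rep(small, "pca_similarity", iterations=25, rng=18).value
        assert lo < hi < 1.0 + 1e-12

    def test_degenerate_data_errors(self):
        pop = simulate_population(random_spd(3, 19), 10, rng=20)
        pop.data.loc[:, pop.trait_names] = 1.0
        with pytest.raises(Exception):
            bootstrap_rep(pop, "pca_similarity", iterations=3, rng=21)

    def test_monte_carlo_rep_converges(self):
        m = random_spd(4, 22)
        est = monte_carlo_rep(m, 10_000, "random_skewers", iterations=20,
                              rng=23)
        assert est.value >= 0.99

    def test_monte_carlo_rep_seeding(self):
        m = random_spd(3, 24)
        a = monte_carlo_rep(m, 50, "pca_similarity", iterations=10, rng=25)
        b = monte_carlo_rep(m, 50, "pca_similarity", iterations=10, rng=25)
        assert a.value == b.value

    def test_weak_structure_mantel_low(self):
        # near-identity matrix: almost no structure to recover, so Mantel
        # repeatability is low; the exact identity is undefined and rejected
        from quantmat import mantel_cor, random_matrix

        weak = random_matrix(4, (0.01, 0.1), rng=26)
        cov = TraitMatrix(weak.values, weak.labels, "covariance")
        est = monte_carlo_rep(cov, 50, "mantel", iterations=15, rng=26)
        assert est.value < 0.6
        eye = TraitMatrix(np.eye(4), list("abcd"), "correlation")
        with pytest.raises(ValidationError):
            mantel_cor(eye, eye, permutations=9, rng=0)


class TestAlphaRep:
    def test_degenerate_equal_offdiagonals(self):
        v = np.full((4, 4), 0.4)
        np.fill_diagonal(v, 1.0)
        m = TraitMatrix(v, list("abcd"), "correlation")
        assert alpha_rep(m, 50).value == 0.0

    def test_large_n_tends_to_one(self, corr_factory):
        m = corr_factory(5, 27)
        assert alpha_rep(m, 10_000_000).value == pytest.approx(1.0, abs=1e-3)
        assert alpha_rep(m, 10_000_000).value < 1.0 + 1e-12

    def test_hand_computed_oracle(self):
        v = np.eye(4)
        elems = [0.1, 0.3, 0.5, 0.2, 0.4, 0.6]
        il = np.tril_indices(4, k=-1)
        v[il] = elems
        v = v + np.tril(v, k=-1).T
        m = TraitMatrix(v, list("abcd"), "correlation")
        var_r = np.var(elems, ddof=1)
        eps2 = (1 - np.mean(elems) ** 2) ** 2 / (50 - 2)
        assert alpha_rep(m, 50).value == pytest.approx((var_r - eps2) / var_r)

    def test_permutation_invariant(self, corr_factory):
        m = corr_factory(6, 28)
        perm = m.reorder(list(np.array(m.labels)[[3, 1, 5, 0, 4, 2]]))
        assert alpha_rep(perm, 40).value == pytest.approx(alpha_rep(m, 40).value)

    def test_tiny_n_rejected(self, corr_factory):
        with pytest.raises(ValidationError):
            alpha_rep(corr_factory(3, 29), 2)


class TestRarefaction:
    def test_full_size_near_one(self):
        pop = simulate_population(random_spd(3, 30), 200, rng=31)
        out = rarefaction(pop, "random_skewers", sizes=[200], iterations=20,
                          rng=32)
        vals = out[200]
        assert 0.9 <= vals.mean() < 1.0

    def test_monotone_in_size_on_average(self):
        pop = simulate_population(random_spd(4, 33), 300, rng=34)
        out = rarefaction(pop, "pca_similarity", sizes=[10, 300],
                          iterations=25, rng=35)
        assert out[10].mean() < out[300].mean()

    def test_seeding_and_size_bounds(self):
        pop = simulate_population(random_spd(3, 36), 50, rng=37)
        a = rarefaction(pop, "pca_similarity", sizes=[20], iterations=5, rng=38)
        b = rarefaction(pop, "pca_similarity", sizes=[20], iterations=5, rng=38)
        np.testing.assert_array_equal(a[20], b[20])
        with pytest.raises(ValidationError):
            rarefaction(pop, "pca_similarity", sizes=[1], iterations=2, rng=39)


class TestExtendMatrix:
    def test_forced_eigenvalues(self):
        m = TraitMatrix(np.diag([10.0, 5.0, 1.0, 0.1, 0.01]),
                        list("abcde"), "covariance")
        out = extend_matrix(m, 3)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(out.values))[::-1],
                                   [10, 5, 1, 1, 1], atol=1e-10)

    def test_full_rank_is_identity_map(self, spd_factory):
        m = spd_factory(5, 40)
        np.testing.assert_allclose(extend_matrix(m, 5).values, m.values,
                                   atol=1e-10)

    def test_leading_structure_preserved(self, spd_factory):
        from quantmat import eigen

        m = spd_factory(6, 41)
        out = extend_matrix(m, 3)
        w0, v0 = eigen(m)
        w1, v1 = eigen(out)
        np.testing.assert_allclose(w1[:3], w0[:3], atol=1e-10)
        # difference is PSD: eigenvalues only ever raised
        diff = out.values - m.values
        assert np.linalg.eigvalsh(diff).min() >= -1e-10

    def test_rank_bounds(self, spd_factory):
        with pytest.raises(ValidationError):
            extend_matrix(spd_factory(4, 42), 0)
        with pytest.raises(ValidationError):
            extend_matrix(spd_factory(4, 42), 5)

    def test_suggested_rank_on_plateau(self):
        m = TraitMatrix(np.diag([10.0, 5.0, 1.0, 1.0 - 1e-6, 1.0 - 2e-6]),
                        list("abcde"), "covariance")
        assert suggest_extension_rank(m) == 3
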