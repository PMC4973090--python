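import numpy as np
import pytest
from scipy import stats as sps

from absdiff_de import CountMatrix, run_test
from absdiff_de.core_test import (
    adjust_bh,
    compute_gene_stats,
    estimate_alpha,
    fit_mean_variance_trend,
    group_sums_with_compensation,
    moderated_mean,
    penalized_dispersion,
    pooled_dispersion,
    pseudocount_moderation,
    pvalue,
    smoothed_variance,
)


def nb_tail_oracle(d, m, r):
    """Brute-force P(X >= d) by pmf summation out to a far tail bound."""
    prob = r / (r + m)
    hi = int(np.ceil(m + 200 * np.sqrt(m + m * m / r))) + 200
    ks = np.arange(d, hi + 1)
    return float(sps.nbinom.pmf(ks, r, prob).sum())


class TestCompensatedSums:
    def test_equal_sizes(self):
        counts = np.array([[10, 20, 5, 5]])
        sa, sb, d = group_sums_with_compensation(counts, np.array([0, 1]), np.array([2, 3]))
        assert (sa[0], sb[0], d[0]) == (30, 10, 20)

    def test_equal_sums_give_zero(self):
        counts = np.array([[7, 3, 4, 6]])
        _, _, d = group_sums_with_compensation(counts, np.array([0, 1]), np.array([2, 3]))
        assert d[0] == 0

    def test_smaller_group_padded_with_its_mean(self):
        # A=(10,20,30) sum 60; B=(8,12) mean 10 -> compensated sum 30; D=30
        counts = np.array([[10, 20, 30, 8, 12]])
        sa, sb, d = group_sums_with_compensation(counts, np.arange(3), np.array([3, 4]))
        assert (sa[0], sb[0], d[0]) == (60, 30, 30)

    def test_statistic_is_integral(self):
        counts = np.array([[10, 21, 30, 8, 12]])  # compensated B sum 30, D=|61-30|
        _, _, d = group_sums_with_compensation(counts, np.arange(3), np.array([3, 4]))
        assert d.dtype == np.int64 and d[0] == 31


class TestPooledDispersion:
    def test_hand_example(self):
        # A=(10,20), B=(5,5): mu=15, s2 sum 50 -> (50-15)/225
        assert pooled_dispersion(np.array([50.0]), np.array([15.0]))[0] == pytest.approx(
            35 / 225
        )

    def test_poisson_like_gene_is_zero(self):
        assert pooled_dispersion(np.array([15.0]), np.array([15.0]))[0] == 0.0

    def test_constant_gene_is_negative(self):
        assert pooled_dispersion(np.array([0.0]), np.array([10.0]))[0] == pytest.approx(-0.1)

    def test_zero_mean_assigned_zero(self):
        assert pooled_dispersion(np.array([3.0]), np.array([0.0]))[0] == 0.0


class TestMeanVarianceTrend:
    def test_constant_dispersion_recovered(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(10, 1000, size=500)
        v = np.full(500, 0.3)
        np.testing.assert_allclose(fit_mean_variance_trend(v, mu), 0.3, atol=1e-3)

    def test_fallback_below_ten_positive_genes(self):
        v = np.array([-0.1, -0.2, 0.4, 0.2, 0.0])
        mu = np.linspace(10, 50, 5)
        np.testing.assert_allclose(fit_mean_variance_trend(v, mu), 0.3)

    def test_no_positive_dispersion_gives_zero(self):
        v = np.array([-0.1, -0.2, 0.0])
        np.testing.assert_allclose(fit_mean_variance_trend(v, np.ones(3)), 0.0)

    def test_recovers_decreasing_trend(self):
        rng = np.random.default_rng(1)
        mu = np.sort(rng.uniform(5, 2000, size=2000))
        true = 0.05 + 8.0 / mu
        v = true * rng.lognormal(0, 0.2, size=mu.size)
        v_hat = fit_mean_variance_trend(v, mu)
        rho = sps.spearmanr(v_hat, true).statistic
        assert rho > 0.9


class TestSmoothedVariance:
    def test_hand_example(self):
        assert smoothed_variance(np.array([10.0]), np.array([0.1]))[0] == pytest.approx(20.0)

    def test_poisson_limit(self):
        assert smoothed_variance(np.array([10.0]), np.array([0.0]))[0] == 10.0

    def test_zero_mean(self):
        assert smoothed_variance(np.array([0.0]), np.array([0.5]))[0] == 0.0


class TestPseudocountModeration:
    def test_theta_is_root_mean_half_variance(self, null_sim):
        # per-gene (s2_A + s2_B) = (2, 8) -> theta = sqrt(mean(1, 4)) = sqrt(2.5)
        cm, _ = null_sim
        stats, globs = compute_gene_stats(cm.counts, *cm.group_indices())
        expected = np.sqrt(np.mean(stats.s2_sum / 2.0))
        assert globs.theta == pytest.approx(expected)

    def test_mu0_hand_example(self):
        mu0, c_hat, mu_hat = pseudocount_moderation(
            np.array([1.0]), np.array([2.0]), np.array([5.0]), n=2, theta=1.0
        )
        assert mu0[0] == pytest.approx(np.sqrt(2.0))
        assert c_hat[0] == pytest.approx(5.0 + 2 * np.sqrt(2.0))
        assert mu_hat[0] == pytest.approx(1.0 + np.sqrt(2.0))

    def test_pseudocount_decreases_with_expression(self):
        # at a given expected variance the 1/mu factor forces smaller
        # pseudocounts for higher-expressed genes
        mu = np.array([1.0, 10.0, 100.0, 1000.0])
        s2_hat = np.full(4, 50.0)
        mu0, _, _ = pseudocount_moderation(mu, s2_hat, mu * 5, n=5, theta=2.0)
        assert np.all(np.diff(mu0) < 0)

    def test_single_replicate_everywhere_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            pseudocount_moderation(np.ones(1), np.ones(1), np.ones(1), n=1, theta=1.0)


class TestPenalizedDispersion:
    def test_hand_example_type7_quantile(self):
        v = np.array([-0.1, -0.1, 0.2, 0.3, 0.4, 0.5])
        v0, beta, v_bar, r_hat = penalized_dispersion(v, np.zeros(6), n=5)
        assert beta == pytest.approx(1 / 3)
        assert v0 == pytest.approx(0.3 + 0.73205 * 0.1, abs=1e-5)
        np.testing.assert_allclose(r_hat, 1.0 / v_bar)

    def test_all_positive_gives_minimum(self):
        v = np.array([0.5, 0.2, 0.9])
        v0, beta, _, _ = penalized_dispersion(v, np.zeros(3), n=2)
        assert beta == 0.0
        assert v0 == pytest.approx(0.2)

    def test_floor_keeps_size_finite(self):
        v = np.array([-5.0])
        _, _, v_bar, r_hat = penalized_dispersion(v, np.zeros(1), n=2)
        assert v_bar[0] == pytest.approx(1e-10)
        assert np.isfinite(r_hat[0])


class TestEstimateAlpha:
    def test_constant_within_groups_hits_floor(self):
        counts = np.array([[4, 4, 9, 9], [2, 2, 7, 7]])
        assert estimate_alpha(counts, np.array([0, 1]), np.array([2, 3])) == 1e-4

    def test_hand_example_residual_sd(self):
        # log2(c+1): A=(1,3), B=(2,2) -> SSR=2, df=2 -> sigma=1
        counts = np.array([[1, 7, 3, 3]])
        alpha = estimate_alpha(counts, np.array([0, 1]), np.array([2, 3]))
        assert alpha == pytest.approx(1.0)

    def test_zero_df_returns_floor(self):
        counts = np.array([[3, 9]])
        assert estimate_alpha(counts, np.array([0]), np.array([1])) == 1e-4


class TestModeratedMean:
    def test_epsilon_hand_example(self):
        eps, _ = moderated_mean(np.zeros(1), np.array([0.0]), np.array([10.0]), n=2, alpha=1.0)
        assert eps[0] == pytest.approx(np.sqrt(20.0))

    def test_m_hat_hand_example(self):
        # c_hat=100, eps=sqrt(4*25)=10, alpha=0.2 -> 22
        eps, m_hat = moderated_mean(
            np.array([100.0]), np.array([0.0]), np.array([25.0]), n=4, alpha=0.2
        )
        assert eps[0] == pytest.approx(10.0)
        assert m_hat[0] == pytest.approx(22.0)

    def test_alpha_zero_degenerates(self):
        _, m_hat = moderated_mean(np.array([100.0]), np.zeros(1), np.ones(1), n=2, alpha=0.0)
        assert m_hat[0] == 0.0


class TestPvalue:
    def test_d_zero_is_one(self):
        assert pvalue(np.array([0]), np.array([10.0]), np.array([2.0]))[0] == 1.0

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = int(rng.integers(0, 200))
            m = float(rng.uniform(0.5, 100))
            r = float(rng.uniform(0.1, 50))
            p = float(pvalue(np.array([d]), np.array([m]), np.array([r]))[0])
            assert p == pytest.approx(nb_tail_oracle(d, m, r), abs=1e-10)

    def test_monotone_in_d(self):
        d = np.arange(0, 100)
        p = pvalue(d, np.full(100, 10.0), np.full(100, 2.0))
        assert np.all(np.diff(p) <= 0)


class TestAdjustBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.3])), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_bh(np.ones(5)), 1.0)

    def test_dominates_raw_pvalues(self, null_sim):
        cm, _ = null_sim
        res = run_test(cm)
        assert np.all(res.padj >= res.pvalue - 1e-12)


class TestRunTest:
    def test_duplicated_groups_are_null(self):
        rng = np.random.default_rng(8)
        block = rng.poisson(40, size=(300, 3))
        counts = np.concatenate([block, block], axis=1)
        cm = CountMatrix(
            counts,
            [f"g{i}" for i in range(300)],
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            dict(zip(["a1", "a2", "a3", "b1", "b2", "b3"], "AAABBB")),
        )
        res = run_test(cm, outlier_filter=False)
        np.testing.assert_array_equal(res.statistic, 0)
        np.testing.assert_array_equal(res.pvalue, 1.0)
        assert int((res.padj < 0.05).sum()) == 0

    def test_null_type_i_error_controlled(self, null_sim):
        cm, _ = null_sim
        res = run_test(cm)
        assert np.mean(res.pvalue < 0.05) <= 0.05

    def test_paired_constant_offsets_have_zero_variance_term(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(100, size=(50, 4))
        b = a + 7  # constant per-pair offset
        counts = np.concatenate([a, b], axis=1)
        ids = [f"a{k}" for k in range(4)] + [f"b{k}" for k in range(4)]
        design = {s: ("A" if s.startswith("a") else "B") for s in ids}
        cm = CountMatrix(counts, [f"g{i}" for i in range(50)], ids, design, paired=True)
        stats, _ = compute_gene_stats(counts, *cm.group_indices(), paired=True)
        np.testing.assert_allclose(stats.s2_sum, 0.0)
        np.testing.assert_array_equal(stats.d, 28)

    def test_moderation_never_more_liberal(self, de_sim):
        cm, _ = de_sim
        idx_a, idx_b = cm.group_indices()
        stats, globs = compute_gene_stats(cm.counts, idx_a, idx_b)
        assert np.all(stats.m_hat >= globs.alpha * stats.c - 1e-9)
        pos = stats.v > 0
        unpenalized = 1.0 / (stats.v[pos] + stats.v_hat[pos] / stats.n)
        assert np.all(stats.r_hat[pos] <= unpenalized + 1e-9)

    def test_invariants_on_gene_stats(self, de_sim):
        cm, _ = de_sim
        stats, _ = compute_gene_stats(cm.counts, *cm.group_indices())
        total = cm.counts.sum(axis=1)
        assert np.all(stats.d <= total)  # equal group sizes: no compensation
        assert np.all(stats.v_bar > 0)
        assert np.all(stats.r_hat > 0)
        assert np.all(stats.c_hat >= stats.c)
        assert np.all(stats.mu_hat >= stats.mu)

    def test_doubling_counts_preserves_factor_ratios(self, null_sim):
        from absdiff_de.normalize import quantile_factors

        cm, _ = null_sim
        f1 = quantile_factors(cm.counts)
        f2 = quantile_factors(cm.counts * 2)
        np.testing.assert_allclose(f2 / f1, 2.0, rtol=1e-12)
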