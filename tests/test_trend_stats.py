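"""Statistical battery: worked values, cross-checks against scipy, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from combotox.trend_stats import (
    OrderedGroups,
    cliffs_delta,
    correlation_suite,
    dunn_posthoc,
    jonckheere_terpstra,
    kruskal_wallis,
    normality_test,
)

rng = np.random.default_rng(20240917)


class TestNormality:
    def test_rejects_gross_bimodality(self):
        x = np.concatenate([rng.normal(-3, 1, 2500), rng.normal(3, 1, 2500)])
        assert normality_test(x).p_value < 0.05

    def test_null_coverage_under_normal_samples(self):
        ps = [normality_test(np.random.default_rng(s).normal(size=5000)).p_value for s in range(200)]
        assert np.mean(np.array(ps) > 0.05) >= 0.95

    def test_matches_scipy_normaltest(self):
        x = rng.gamma(2.0, size=300)
        res = normality_test(x)
        k2, p = stats.normaltest(x)
        assert res.statistic == pytest.approx(k2)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("bad", [np.arange(10), np.ones(50)])
    def test_small_or_degenerate_samples_rejected(self, bad):
        with pytest.raises(ValueError):
            normality_test(bad)


class TestKruskalWallis:
    def test_worked_example_no_ties(self):
        # ranks 1..9 split evenly: H = 7.2, eta2 = H/(N-1) = 0.9
        res = kruskal_wallis(OrderedGroups([[1, 2, 3], [4, 5, 6], [7, 8, 9]]))
        assert res.statistic == pytest.approx(7.2)
        assert res.effect_size == pytest.approx(0.9)

    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis(OrderedGroups([[1, 2, 3], [1, 2, 3]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        r = np.random.default_rng(seed)
        groups = [r.integers(0, 6, size=n).astype(float) for n in (12, 17, 9)]
        res = kruskal_wallis(OrderedGroups(groups))
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis(OrderedGroups([[2, 2, 2], [2, 2, 2]]))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_h_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        groups = [r.normal(size=8), r.normal(1, 1, size=8), r.normal(size=8)]
        h0 = kruskal_wallis(OrderedGroups(groups)).statistic
        h1 = kruskal_wallis(OrderedGroups([np.exp(g) for g in groups])).statistic
        assert h0 == pytest.approx(h1)


class TestCliffsDelta:
    def test_enumerated_example(self):
        assert cliffs_delta([1, 2], [1, 3]) == pytest.approx(-0.25)

    def test_complete_dominance(self):
        assert cliffs_delta([5, 6, 7], [1, 2]) == 1.0

    def test_identical_multisets_zero(self):
        assert cliffs_delta([1, 2, 2, 3], [1, 2, 2, 3]) == 0.0

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.integers(0, 5, 11).astype(float), r.integers(0, 5, 7).astype(float)
        d = cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-cliffs_delta(y, x))

    def test_brute_force_oracle(self):
        r = np.random.default_rng(7)
        x, y = r.integers(0, 4, 20).astype(float), r.integers(0, 4, 15).astype(float)
        brute = np.mean(np.sign(x[:, None] - y[None, :]))
        assert cliffs_delta(x, y) == pytest.approx(brute)


class TestDunn:
    def test_three_groups_give_three_contrasts(self):
        res = dunn_posthoc(OrderedGroups([[1, 2, 5], [2, 3, 8], [9, 10, 11]]))
        assert len(res) == 3
        assert all(0 <= r.p_value <= 1 for r in res)

    def test_separated_pair_has_smallest_p(self):
        g = OrderedGroups(
            [[1, 2, 3, 4, 5], [3, 4, 5, 6, 7], [30, 31, 32, 33, 34]],
            ["Minor", "Moderate", "Major"],
        )
        res = dunn_posthoc(g)
        by_pair = {r.notes.split(";")[0]: r.p_value for r in res}
        assert min(by_pair, key=by_pair.get) == "Minor vs Major"

    @pytest.mark.parametrize("seed", range(4))
    def test_two_group_z_equals_tie_corrected_mwu_z(self, seed):
        """For k=2 Dunn's z must coincide with the asymptotic rank-sum z."""
        r = np.random.default_rng(seed)
        x, y = r.integers(0, 8, 25).astype(float), r.integers(2, 10, 18).astype(float)
        d = dunn_posthoc(OrderedGroups([x, y]))[0]
        ref = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert min(1.0, ref.pvalue) == pytest.approx(d.p_value)

    def test_effect_size_is_cliffs_delta(self):
        g = OrderedGroups([[1, 2], [1, 3], [4, 5]])
        res = dunn_posthoc(g)
        assert res[0].effect_size == pytest.approx(cliffs_delta([1, 2], [1, 3]))


class TestJonckheereTerpstra:
    def test_maximal_arrangement(self):
        g = OrderedGroups([[1, 2], [3, 4], [5, 6]])
        res = jonckheere_terpstra(g, "increasing")
        assert res.statistic == 12  # every between-group pair concordant

    def test_exhaustive_permutation_p(self):
        g = OrderedGroups([[1, 2], [3, 4], [5, 6]])
        res = jonckheere_terpstra(g, "increasing", mode="permutation")
        # 6!/(2!2!2!) = 90 distinct assignments; only the observed one reaches J=12
        assert res.p_value == pytest.approx(1 / 90)

    def test_decreasing_alternative_complementary(self):
        g = OrderedGroups([[1, 2], [3, 4], [5, 6]])
        assert jonckheere_terpstra(g, "decreasing").p_value >= 0.95

    def test_label_reversal_flips_sign_and_swaps_directions(self):
        r = np.random.default_rng(3)
        g = OrderedGroups([r.normal(m, 1, 15) for m in (0.0, 0.4, 0.9)])
        inc = jonckheere_terpstra(g, "increasing")
        dec_rev = jonckheere_terpstra(g.reversed(), "decreasing")
        assert inc.effect_size == pytest.approx(-dec_rev.effect_size)
        assert inc.p_value == pytest.approx(dec_rev.p_value)

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_approx_close_to_permutation(self, seed):
        r = np.random.default_rng(seed)
        g = OrderedGroups([r.normal(size=n) for n in (6, 7, 5)])
        approx = jonckheere_terpstra(g, "increasing").p_value
        perm = jonckheere_terpstra(g, "increasing", mode="permutation", n_perm=20000, rng=seed).p_value
        assert abs(approx - perm) < 0.02

    def test_tie_handling_half_weight(self):
        # g1=[1,2], g2=[2,3]: pairs (1,2)<,(1,3)<,(2,2)=,(2,3)< -> J = 3 + 0.5
        g = OrderedGroups([[1, 2], [2, 3]])
        assert jonckheere_terpstra(g, "increasing").statistic == pytest.approx(3.5)

    def test_empty_group_and_constant_data_errors(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra(OrderedGroups([[1, 2], []]))
        with pytest.raises(ValueError):
            jonckheere_terpstra(OrderedGroups([[1, 1], [1, 1]]))


class TestCorrelationSuite:
    def test_perfect_line(self):
        x = np.arange(10.0)
        out = correlation_suite(x, 2 * x + 1)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)

    def test_monotone_nonlinear_transform(self):
        x = np.linspace(0, 5, 50)
        y = np.exp(x)
        out = correlation_suite(x, y)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["pearson_r"] < 1.0

    def test_independent_samples_near_zero(self):
        r = np.random.default_rng(11)
        out = correlation_suite(r.normal(size=10000), r.normal(size=10000))
        assert abs(out["pearson_r"]) < 0.05

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            correlation_suite([1, 1, 1], [1, 2, 3])
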