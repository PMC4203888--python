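"""Divergence statistics: Welch tests, FDR, top-set overlap, rank concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendrodiv import divergence_stats as dvs
from oracles import bh_stepup, median_rank_top_brute, welch_direct


def frame(arr, prefix):
    arr = np.atleast_2d(np.asarray(arr, float))
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        a = frame([[1.0, 2.0, 3.0]], "A")
        b = frame([[1.0, 2.0, 3.0]], "B")
        tab = dvs.welch_ttest_table(a, b)
        assert tab["t_stat"].iloc[0] == pytest.approx(0.0)
        assert tab["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_equal_means_p1(self):
        tab = dvs.welch_ttest_table(frame([[2.0, 2.0]], "A"), frame([[2.0, 2.0, 2.0]], "B"))
        assert tab["p_value"].iloc[0] == 1.0 and tab["t_stat"].iloc[0] == 0.0

    def test_separation_limit(self):
        eps = 1e-8
        a = frame([[0.0, eps, -eps]], "A")
        b = frame([[1.0, 1.0 + eps, 1.0 - eps]], "B")
        assert dvs.welch_ttest_table(a, b)["p_value"].iloc[0] < 1e-10

    def test_matches_direct_formula_oracle(self, rng):
        a = rng.normal(0, 1, (50, 9))
        b = rng.normal(0.5, 2, (50, 14))
        tab = dvs.welch_ttest_table(frame(a, "A"), frame(b, "B"))
        for i in range(50):
            t, p = welch_direct(a[i], b[i])
            assert tab["t_stat"].iloc[i] == pytest.approx(t)
            assert tab["p_value"].iloc[i] == pytest.approx(p)

    def test_planted_shift_rejection_rate_matches_oracle(self, rng):
        # delta = 2 sigma, 9 vs 14 replicates: the module and the direct
        # formula must flag identical gene sets
        a = rng.normal(0, 1, (2000, 9))
        b = rng.normal(0, 1, (2000, 14))
        b[:400] += 2.0
        tab = dvs.welch_ttest_table(frame(a, "A"), frame(b, "B"), q=0.001)
        p_oracle = np.array([welch_direct(a[i], b[i])[1] for i in range(2000)])
        assert np.array_equal(tab["q_flag"].to_numpy(), bh_stepup(p_oracle, 0.001))

    def test_too_few_replicates_is_error(self):
        with pytest.raises(ValueError, match="replicate"):
            dvs.welch_ttest_table(frame([[1.0]], "A"), frame([[1.0, 2.0]], "B"))


class TestBhFdr:
    def test_all_p_one_rejects_nothing(self):
        reject, _ = dvs.bh_fdr([1.0] * 10, q=0.05)
        assert not reject.any()

    def test_stepup_enumeration_example(self):
        # max i with p(i) <= i*q/4 is i = 4 -> all rejected
        reject, _ = dvs.bh_fdr([0.001, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_on_random_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.beta(0.5, 3.0, 300)
        reject, _ = dvs.bh_fdr(p, q=0.05)
        assert np.array_equal(reject, bh_stepup(p, 0.05))

    def test_flags_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        reject, _ = dvs.bh_fdr(p, q=0.1)
        if reject.any():
            assert p[reject].max() <= p[~reject].min() or not (~reject).any()

    def test_null_simulation_rarely_rejects(self):
        rng = np.random.default_rng(11)
        n_runs_with_rejection = 0
        for _ in range(20):
            a = rng.normal(0, 1, (5000, 9))
            b = rng.normal(0, 1, (5000, 14))
            p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
            reject, _ = dvs.bh_fdr(p, q=0.001)
            n_runs_with_rejection += reject.any()
        assert n_runs_with_rejection <= 2

    def test_invalid_p_is_error(self):
        with pytest.raises(ValueError):
            dvs.bh_fdr([0.5, 1.5], q=0.05)


class TestTopSets:
    def test_distinct_values_give_exactly_top_fraction(self, rng):
        vals = rng.permutation(100).astype(float)
        expr = frame(np.column_stack([vals, vals, vals]), "A")
        top = dvs.median_rank_top_set(expr, 0.05)
        assert top == {f"g{i}" for i in np.argsort(-vals)[:5]}

    def test_invariant_to_replicate_order(self, rng):
        x = rng.normal(size=(60, 4))
        expr = frame(x, "A")
        shuffled = frame(x[:, ::-1], "A")
        assert dvs.median_rank_top_set(expr, 0.1) == dvs.median_rank_top_set(shuffled, 0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_conflicting_orders_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, size=(40, 3)).astype(float)  # heavy ties
        got = dvs.median_rank_top_set(frame(x, "A"), 0.2)
        want = {f"g{i}" for i in median_rank_top_brute(x, 0.2)}
        assert got == want

    def test_overlap_fraction_bounds(self):
        assert dvs.overlap_fraction({"a", "b"}, {"a", "b"}) == 1.0
        assert dvs.overlap_fraction({"a"}, {"b"}) == 0.0
        with pytest.raises(ValueError):
            dvs.overlap_fraction(set(), {"a"}, denominator="A")

    def test_asymmetric_denominators(self):
        a, b = {"x", "y", "z"}, {"x"}
        assert dvs.overlap_fraction(a, b, "A") == pytest.approx(1 / 3)
        assert dvs.overlap_fraction(a, b, "B") == pytest.approx(1.0)

    def test_random_sets_overlap_near_fraction(self, rng):
        # independent top-5% sets from N = 3839 orthologs
        n, k = 3839, 191
        overlaps = []
        for _ in range(200):
            sa = set(rng.choice(n, k, replace=False))
            sb = set(rng.choice(n, k, replace=False))
            overlaps.append(dvs.overlap_fraction(sa, sb))
        assert np.mean(overlaps) == pytest.approx(k / n, abs=0.005)


class TestOverlapMatrix:
    def test_identical_matrices_give_all_ones(self, rng):
        x = frame(rng.normal(size=(100, 3)), "A")
        mats = {"t1": x, "t2": x.copy(), "t3": x.copy()}
        out = dvs.overlap_matrix(mats, 0.05)
        assert np.allclose(out.to_numpy(dtype=float), 1.0)

    def test_planted_shared_top_set(self, rng):
        # two tissues share s = 3 of their floor(0.05*100) = 5 top genes
        n = 100
        base = np.zeros(n)
        x1, x2 = base.copy(), base.copy()
        x1[[0, 1, 2, 3, 4]] = [10, 9, 8, 7, 6]
        x2[[0, 1, 2, 50, 60]] = [10, 9, 8, 7, 6]
        jitter = rng.normal(0, 1e-6, n)
        mats = {
            "t1": frame(np.column_stack([x1 + jitter, x1 + jitter]), "A"),
            "t2": frame(np.column_stack([x2 + jitter, x2 + jitter]), "A"),
        }
        out = dvs.overlap_matrix(mats, 0.05)
        assert out.loc["t1", "t2"] == pytest.approx(3 / 5)

    def test_permuted_tissue_near_random_level(self, rng):
        n = 2000
        x = rng.normal(size=n)
        perm = rng.permutation(n)
        mats = {
            "t1": frame(np.column_stack([x, x]), "A"),
            "t2": frame(np.column_stack([x[perm], x[perm]]), "A"),
        }
        out = dvs.overlap_matrix(mats, 0.05)
        assert out.loc["t1", "t2"] < 0.15

    def test_mismatched_universe_is_error(self, rng):
        m1 = frame(rng.normal(size=(10, 2)), "A")
        m2 = m1.iloc[:5]
        with pytest.raises(ValueError, match="universe"):
            dvs.overlap_matrix({"a": m1, "b": m2})


class TestArcsineTest:
    def test_equal_to_reference_gives_p1(self):
        t, p = dvs.arcsine_one_sample_test(0.19, [0.19, 0.19, 0.19])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_toy(self):
        tissues = np.array([0.55, 0.60, 0.58])
        ref = 0.19
        z = np.arcsin(np.sqrt(tissues))
        expect_t = (z.mean() - np.arcsin(np.sqrt(ref))) / (z.std(ddof=1) / np.sqrt(3))
        expect_p = 2 * stats.t.sf(abs(expect_t), 2)
        t, p = dvs.arcsine_one_sample_test(ref, tissues)
        assert t == pytest.approx(expect_t) and p == pytest.approx(expect_p)

    def test_null_type_i_error_near_nominal(self):
        # tissue overlaps scatter around the reference value: rejection rate
        # at alpha = 0.05 should sit at the nominal level within MC error
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            tissues = np.clip(rng.normal(0.4, 0.05, 8), 0, 1)
            _, p = dvs.arcsine_one_sample_test(0.4, tissues)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_out_of_range_fraction_is_error(self):
        with pytest.raises(ValueError):
            dvs.arcsine_one_sample_test(0.5, [0.2, 1.2])


class TestConcordance:
    def series(self, vals):
        return pd.Series(np.asarray(vals, float), index=range(len(vals)))

    def test_identity_ranking_is_one_everywhere(self, rng):
        x = self.series(rng.permutation(600))
        curve = dvs.rank_concordance_curve(x, x.copy(), k_min=31, k_max=500)
        assert np.allclose(curve.concordance, 1.0)

    def test_reversed_ranking_is_zero_at_k100(self):
        x = self.series(np.arange(600))
        y = self.series(-np.arange(600))
        curve = dvs.rank_concordance_curve(x, y, k_min=100, k_max=100)
        assert curve.concordance[0] == 0.0

    def test_independent_rankings_near_k_over_n(self, rng):
        n = 3839
        a = self.series(rng.permutation(n))
        b = self.series(rng.permutation(n))
        curve = dvs.rank_concordance_curve(a, b, 31, 500)
        expected = curve.k / n
        inside = (curve.ci_low <= expected) & (expected <= curve.ci_high)
        assert inside.mean() >= 0.99

    def test_k_max_too_large_is_error(self):
        x = self.series(np.arange(100))
        with pytest.raises(ValueError, match="k_max"):
            dvs.rank_concordance_curve(x, x, 31, 100)


class TestBinomialCi:
    def test_boundaries(self):
        low, high = dvs.binomial_ci_bonferroni(10, 10)
        assert high == 1.0
        low, high = dvs.binomial_ci_bonferroni(0, 10)
        assert low == 0.0

    def test_beta_quantile_oracle(self):
        x, n, level, factor = 50, 100, 0.95, 500
        alpha = (1 - level) / factor
        want_low = stats.beta.ppf(alpha / 2, x, n - x + 1)
        want_high = stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
        low, high = dvs.binomial_ci_bonferroni(x, n, level, factor)
        assert low == pytest.approx(want_low) and high == pytest.approx(want_high)
        assert low <= x / n <= high

    def test_n_zero_is_error(self):
        with pytest.raises(ValueError):
            dvs.binomial_ci_bonferroni(0, 0)


class TestTwoProportion:
    def test_equal_proportions_give_p1(self):
        assert dvs.two_proportion_test(5, 10, 10, 20) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["z-pooled", "chisq", "exact"])
    def test_snp_counts_not_significant(self, method):
        # 29 SNPs in 54 divergent genes vs 25 in 54 similar genes
        assert dvs.two_proportion_test(29, 54, 25, 54, method=method) > 0.05

    def test_extreme_separation(self):
        assert dvs.two_proportion_test(50, 50, 0, 50) < 1e-10

    def test_z_and_chisq_agree(self):
        pz = dvs.two_proportion_test(12, 40, 20, 45, "z-pooled")
        pc = dvs.two_proportion_test(12, 40, 20, 45, "chisq")
        assert pz == pytest.approx(pc)

    def test_zero_n_is_error(self):
        with pytest.raises(ValueError):
            dvs.two_proportion_test(0, 0, 1, 10)
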