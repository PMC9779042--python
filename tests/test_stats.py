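import numpy as np
import pytest
import scipy.stats as sps

from zeitfly import stats as zs


def rank_with_midranks(values):
    """Independent mid-rank assignment via sorting (test-local oracle)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    return ranks


class TestDagostinoPearson:
    def test_null_calibration(self):
        x = np.random.default_rng(1).normal(size=5000)
        assert zs.dagostino_pearson(x).p > 0.01

    def test_lognormal_rejected(self):
        x = np.exp(np.random.default_rng(2).normal(size=500))
        assert zs.dagostino_pearson(x).p < 0.001

    def test_constant_sample_error(self):
        with pytest.raises(ValueError, match="constant"):
            zs.dagostino_pearson(np.full(20, 3.0))

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            zs.dagostino_pearson(np.arange(5.0))

    @pytest.mark.parametrize("n", [8, 20, 100, 999])
    def test_matches_scipy_normaltest(self, n, rng):
        x = rng.normal(size=n) + rng.exponential(size=n)
        r = zs.dagostino_pearson(x)
        k2, p = sps.normaltest(x)
        assert r.statistic == pytest.approx(k2, abs=1e-9)
        assert r.p == pytest.approx(p, abs=1e-9)


class TestLogTransformGate:
    def test_normal_unchanged(self, rng):
        x = rng.normal(10, 1, 200)
        g = zs.log_transform_gate(x)
        assert g.branch == "parametric" and not g.transformed
        assert np.array_equal(g.values, x)

    def test_lognormal_goes_log(self, rng):
        x = np.exp(rng.normal(size=300))
        g = zs.log_transform_gate(x)
        assert g.branch == "parametric-log" and g.transformed

    def test_zero_blocks_log_branch(self, rng):
        x = np.exp(rng.normal(size=300))
        x[0] = 0.0
        assert zs.log_transform_gate(x).branch == "nonparametric"


class TestKruskalWallis:
    def test_identical_values_h_zero(self):
        r = zs.kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_untied_small_groups_hand_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        # no ties: ranks are the values themselves; H by the raw rank formula
        n = 9
        rank_sums = [6, 15, 24]
        h_expected = 12 / (n * (n + 1)) * sum(rs**2 / 3 for rs in rank_sums) - 3 * (n + 1)
        r = zs.kruskal_wallis(groups)
        assert r.statistic == pytest.approx(h_expected, abs=1e-9)

    def test_tied_data_matches_scipy(self, rng):
        groups = [rng.integers(0, 4, 15).astype(float) for _ in range(4)]
        r = zs.kruskal_wallis(groups)
        h, p = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(h, abs=1e-9)
        assert r.p == pytest.approx(p, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=12) for _ in range(3)]
        h0 = zs.kruskal_wallis(groups).statistic
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert zs.kruskal_wallis([f(g) for g in groups]).statistic == pytest.approx(
                h0, abs=1e-12
            )

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            zs.kruskal_wallis([[1.0, 2.0]])


class TestDunn:
    def test_identical_groups_z_zero(self):
        out = zs.dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert out[0].statistic == 0.0 and out[0].p_adj == 1.0

    def test_brute_force_rank_oracle(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [7.0, 8.0, 9.0]]
        pooled = np.concatenate(groups)
        ranks = rank_with_midranks(pooled)
        rbars = [ranks[0:3].mean(), ranks[3:6].mean(), ranks[6:9].mean()]
        n = 9
        var = n * (n + 1) / 12.0  # no ties
        out = zs.dunn_posthoc(groups)
        k = 0
        for i in range(3):
            for j in range(i + 1, 3):
                z = (rbars[i] - rbars[j]) / np.sqrt(var * (1 / 3 + 1 / 3))
                assert out[k].statistic == pytest.approx(z, abs=1e-9)
                k += 1

    def test_adjusted_p_at_least_raw(self, rng):
        groups = [rng.normal(loc=m, size=10) for m in (0, 0.5, 2.0)]
        for adj in ("bonferroni", "holm", "sidak"):
            for c in zs.dunn_posthoc(groups, adjustment=adj):
                assert c.p_adj >= c.p_raw - 1e-15

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            zs.dunn_posthoc([[1.0, 2.0]])


class TestOneWayAnova:
    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.4, 1.0, 15)
        r = zs.one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert r.statistic == pytest.approx(t**2, abs=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        pvals = [
            zs.one_way_anova([rng.normal(size=15) for _ in range(3)]).p
            for _ in range(500)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_within_variance_error(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            zs.one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_tukey_ordering_consistent_with_mean_shifts(self, rng):
        groups = [rng.normal(loc=m, size=20) for m in (0.0, 1.0, 3.0)]
        out = {(c.a, c.b): c for c in zs.tukey_hsd(groups, ["g0", "g1", "g2"])}
        assert out[("g0", "g2")].statistic > out[("g0", "g1")].statistic
        assert out[("g0", "g2")].p_adj < out[("g0", "g1")].p_adj

    def test_tukey_matches_scipy(self, rng):
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.7, 1.1)]
        ours = zs.tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        k = 0
        for i in range(3):
            for j in range(i + 1, 3):
                assert ours[k].p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-7)
                k += 1


class TestTwoWayAnova:
    @staticmethod
    def balanced_textbook_ss(y, a_codes, b_codes, na, nb, reps):
        grand = y.mean()
        ss_a = sum(
            nb * reps * (y[a_codes == i].mean() - grand) ** 2 for i in range(na)
        )
        ss_b = sum(
            na * reps * (y[b_codes == j].mean() - grand) ** 2 for j in range(nb)
        )
        ss_cells = 0.0
        for i in range(na):
            for j in range(nb):
                cell = y[(a_codes == i) & (b_codes == j)]
                ss_cells += reps * (cell.mean() - grand) ** 2
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((y - y.mean()) ** 2).sum() - ss_cells
        return ss_a, ss_b, ss_ab, ss_err

    def test_balanced_matches_textbook_decomposition(self, rng):
        na, nb, reps = 2, 3, 5
        a = np.repeat(np.arange(na), nb * reps)
        b = np.tile(np.repeat(np.arange(nb), reps), na)
        y = rng.normal(size=na * nb * reps) + 0.5 * a + 0.3 * b
        r = zs.two_way_anova(y, a, b)
        ss_a, ss_b, ss_ab, ss_err = self.balanced_textbook_ss(y, a, b, na, nb, reps)
        assert r.extras["ss"]["A"] == pytest.approx(ss_a, abs=1e-9)
        assert r.extras["ss"]["B"] == pytest.approx(ss_b, abs=1e-9)
        assert r.extras["ss"]["A:B"] == pytest.approx(ss_ab, abs=1e-9)
        assert r.extras["ss"]["error"] == pytest.approx(ss_err, abs=1e-9)

    def test_unbalanced_matches_statsmodels_type2(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 60
        a = rng.choice(["x", "y"], n)
        b = rng.choice(["u", "v", "w"], n)
        y = rng.normal(size=n) + (a == "y") * 0.8
        r = zs.two_way_anova(y, a, b)
        tab = sm.stats.anova_lm(
            ols("y ~ C(a)*C(b)", pd.DataFrame({"y": y, "a": a, "b": b})).fit(), typ=2
        )
        for eff, key in zip(r.effects, ["C(a)", "C(b)", "C(a):C(b)"]):
            assert eff.statistic == pytest.approx(tab.loc[key, "F"], rel=1e-9)
            assert eff.p == pytest.approx(tab.loc[key, "PR(>F)"], rel=1e-9)

    def test_additive_effects_rarely_flag_interaction(self):
        rng = np.random.default_rng(7)
        n_flag = 0
        reps = 200
        for _ in range(reps):
            a = np.repeat([0, 1], 30)
            b = np.tile(np.repeat([0, 1, 2], 10), 2)
            y = rng.normal(size=60) + a * 1.0 + b * 0.5
            if zs.two_way_anova(y, a, b).effects[2].p <= 0.05:
                n_flag += 1
        assert n_flag <= 0.10 * reps

    def test_one_observation_per_cell_error(self):
        with pytest.raises(ValueError, match="interaction untestable"):
            zs.two_way_anova([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], [0, 1, 0, 1])

    def test_empty_cell_error_names_cell(self):
        with pytest.raises(ValueError, match="empty cells"):
            zs.two_way_anova(
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                ["a", "a", "a", "a", "b", "b"],
                ["u", "u", "v", "v", "u", "u"],
            )


class TestScheirerRayHare:
    def test_factor_a_shift_detected(self, rng):
        a = np.repeat([0, 1], 20)
        b = np.tile([0, 1], 20)
        y = rng.normal(size=40) + a * 5.0
        r = zs.scheirer_ray_hare(y, a, b)
        h_a, h_b = r.effects[0], r.effects[1]
        assert h_a.p < 0.001
        assert h_b.statistic < h_a.statistic / 10

    def test_all_equal_all_zero(self):
        r = zs.scheirer_ray_hare([2.0] * 12, np.repeat([0, 1], 6), np.tile([0, 1], 6))
        assert all(e.statistic == 0.0 for e in r.effects)

    def test_2x2_hand_rank_oracle(self):
        # balanced 2x2 with 2 replicates; full hand computation on ranks
        y = np.array([1.0, 2.0, 5.0, 6.0, 3.0, 4.0, 7.0, 9.0])
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        ranks = rank_with_midranks(y)  # 1..8, no ties
        grand = ranks.mean()
        ss_a = sum(4 * (ranks[a == i].mean() - grand) ** 2 for i in (0, 1))
        ss_b = sum(4 * (ranks[b == j].mean() - grand) ** 2 for j in (0, 1))
        ss_cells = 0.0
        for i in (0, 1):
            for j in (0, 1):
                ss_cells += 2 * (ranks[(a == i) & (b == j)].mean() - grand) ** 2
        ss_ab = ss_cells - ss_a - ss_b
        ms_total = ((ranks - grand) ** 2).sum() / (len(y) - 1)
        r = zs.scheirer_ray_hare(y, a, b)
        assert r.effects[0].statistic == pytest.approx(ss_a / ms_total, abs=1e-9)
        assert r.effects[1].statistic == pytest.approx(ss_b / ms_total, abs=1e-9)
        assert r.effects[2].statistic == pytest.approx(ss_ab / ms_total, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        a = np.repeat([0, 1], 10)
        b = np.tile([0, 1], 10)
        y = rng.normal(size=20)
        r0 = zs.scheirer_ray_hare(y, a, b)
        r1 = zs.scheirer_ray_hare(np.exp(y), a, b)
        for e0, e1 in zip(r0.effects, r1.effects):
            assert e0.statistic == pytest.approx(e1.statistic, abs=1e-12)


class TestWilcoxonFamily:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert zs.wilcoxon_signed_rank(x, x).p == 1.0

    def test_all_tied_day_p_one(self):
        assert zs.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0]).p == 1.0

    def test_signed_rank_matches_scipy_approx(self, rng):
        x, y = rng.normal(size=30), rng.normal(0.3, 1.0, 30)
        r = zs.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=False, mode="approx")
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_mann_whitney_matches_scipy_asymptotic(self, rng):
        x, y = rng.normal(size=25), rng.normal(0.5, 1.0, 20)
        r = zs.mann_whitney(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_bh_step_up_hand_case(self):
        adj = zs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=20)
        adj = zs.benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)

    def test_wilcoxon_bh_pipeline(self, rng):
        days = [(rng.normal(size=15), rng.normal(size=15)) for _ in range(4)]
        out = zs.wilcoxon_bh(days, paired=True)
        assert len(out) == 4
        raws = [r for r, _ in out]
        assert np.allclose([a for _, a in out], zs.benjamini_hochberg(raws))


class TestCalibrationAndDispatch:
    def test_type_one_error_calibration(self):
        # null: identical groups, n=20, alpha 0.05 -> rejection in [0.04, 0.06]
        rng = np.random.default_rng(99)
        reps = 2000
        rej_kw = rej_f = 0
        for _ in range(reps):
            groups = [rng.normal(size=20) for _ in range(3)]
            if zs.kruskal_wallis(groups).p < 0.05:
                rej_kw += 1
            if zs.one_way_anova(groups).p < 0.05:
                rej_f += 1
        assert 0.04 <= rej_kw / reps <= 0.06
        assert 0.04 <= rej_f / reps <= 0.06

    def test_dispatch_normal_parametric(self, rng):
        groups = [rng.normal(10, 1, 50) for _ in range(3)]
        assert zs.select_test(groups).branch == "parametric"

    def test_dispatch_lognormal_log_branch(self, rng):
        groups = [np.exp(rng.normal(0, 1, 200)) for _ in range(3)]
        assert zs.select_test(groups).branch == "parametric-log"

    def test_dispatch_nonparametric_fallback(self, rng):
        # heavy-tailed signed data: neither raw nor log is available/normal
        groups = [rng.standard_cauchy(100) for _ in range(3)]
        assert zs.select_test(groups).branch == "nonparametric"


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00005, "****")],
    )
    def test_tiers(self, p, expected):
        assert zs.significance_stars(p) == expected
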