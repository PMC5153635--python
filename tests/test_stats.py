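import numpy as np
import pandas as pd
import pytest

from docnet import stats
from docnet.errors import UnstableResolutionWarning


def _two_way_table(rng, n_groups=(11, 7, 11), n_networks=10, state_shift=0.0):
    rows = []
    sid = 0
    for g, n in zip(("VS_UWS", "MCS", "CONTROL"), n_groups):
        for _ in range(n):
            for k in range(n_networks):
                val = rng.standard_normal()
                if g == "VS_UWS":
                    val += state_shift
                rows.append({"subject": f"s{sid}", "state": g,
                             "network": f"net{k}", "value": val})
            sid += 1
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_study_sized_degrees_of_freedom(self, rng):
        table = _two_way_table(rng)
        res = stats.two_way_anova(table)
        assert res["state"].df == (2, 260)
        assert res["network"].df == (9, 260)
        assert res["state:network"].df == (18, 260)

    def test_constant_values_give_zero_f(self, rng):
        table = _two_way_table(rng)
        table["value"] = 1.0
        res = stats.two_way_anova(table)
        for r in res.values():
            assert r.f == pytest.approx(0.0, abs=1e-20)

    def test_planted_state_effect_is_powerful(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            table = _two_way_table(rng, state_shift=1.0)
            res = stats.two_way_anova(table)
            hits += res["state"].p < 0.01
        assert hits >= 19

    def test_sums_of_squares_additive(self, rng):
        table = _two_way_table(rng, state_shift=0.5)
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        model = ols("value ~ C(state) * C(network)", data=table).fit()
        aov = anova_lm(model, typ=1)
        ss = aov["sum_sq"]
        total = ((table["value"] - table["value"].mean()) ** 2).sum()
        assert ss.sum() == pytest.approx(total, rel=1e-8)

    def test_missing_cell_rejected(self, rng):
        table = _two_way_table(rng)
        table = table[~((table.state == "MCS") & (table.network == "net3"))]
        with pytest.raises(ValueError):
            stats.two_way_anova(table)


class TestTukeyPosthoc:
    def test_identical_groups_not_significant(self, rng):
        base = rng.standard_normal(10)
        vals = np.concatenate([base, base])
        groups = ["A"] * 10 + ["B"] * 10
        res = stats.tukey_posthoc(vals, groups)
        assert res[("A", "B")][1] > 0.99

    def test_shifted_group_detected(self, rng):
        vals = np.concatenate([
            rng.standard_normal(10),
            rng.standard_normal(10),
            rng.standard_normal(10) + 5.0,
        ])
        groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        res = stats.tukey_posthoc(vals, groups)
        assert res[("A", "C")][1] < 0.01
        assert res[("B", "C")][1] < 0.01
        assert res[("A", "B")][1] > 0.05

    def test_adjusted_p_not_below_unadjusted(self, rng):
        from scipy.stats import ttest_ind

        vals = np.concatenate([
            rng.standard_normal(8), rng.standard_normal(8) + 1.0,
            rng.standard_normal(8)])
        groups = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        res = stats.tukey_posthoc(vals, groups)
        raw = ttest_ind(vals[:8], vals[8:16]).pvalue
        assert res[("A", "B")][1] >= raw - 1e-12

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            stats.tukey_posthoc(np.arange(4.0), ["A", "A", "A", "B"])


class TestBaselineCorrelation:
    def test_exact_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, pb = stats.baseline_correlation(a, -a, 0.5, -0.5)
        assert r == pytest.approx(-1.0)

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(3)
        # weakly correlated data -> moderate p, multiplied by m
        a = rng.standard_normal(20)
        b = 0.5 * a + rng.standard_normal(20)
        r, p, pb = stats.baseline_correlation(a, b, 0.0, 0.0, m_comparisons=3)
        assert pb == pytest.approx(min(1.0, 3 * p))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.baseline_correlation(np.ones(5), np.arange(5.0), 0.0, 0.0)


class TestNodalPermutationTest:
    @staticmethod
    def _data(rng, n=(6, 5, 6), nodes=12, shift_node=None, shift=0.0):
        groups = ["VS_UWS"] * n[0] + ["MCS"] * n[1] + ["CONTROL"] * n[2]
        data = rng.standard_normal((sum(n), nodes, 3))
        if shift_node is not None:
            data[: n[0], shift_node, :] += shift
        return data, groups

    def test_null_cohort_few_discoveries(self):
        rng = np.random.default_rng(8)
        frac = []
        for _ in range(10):
            data, groups = self._data(rng)
            res = stats.nodal_permutation_test(data, groups, n_perm=200)
            frac.append(np.mean(res.q < 0.05))
        assert np.mean(frac) < 0.02

    def test_planted_node_is_top_ranked(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(50 + s)
            data, groups = self._data(rng, shift_node=4, shift=2.0)
            res = stats.nodal_permutation_test(data, groups, n_perm=200, seed=s)
            hits += int(np.argmin(res.p)) == 4 or res.p[4] == res.p.min()
        assert hits >= 8

    def test_p_resolution_matches_permutation_count(self, rng):
        data, groups = self._data(rng, shift_node=2, shift=4.0)
        res = stats.nodal_permutation_test(data, groups, n_perm=500, seed=0)
        nonzero = res.p[res.p > 0]
        if nonzero.size:
            assert nonzero.min() >= 1.0 / 500

    def test_low_permutation_count_warns(self, rng):
        data, groups = self._data(rng)
        with pytest.warns(UnstableResolutionWarning):
            stats.nodal_permutation_test(data, groups, n_perm=50)

    def test_fdr_monotone_in_sorted_order(self, rng):
        data, groups = self._data(rng, shift_node=1, shift=1.0)
        res = stats.nodal_permutation_test(data, groups, n_perm=300, seed=2)
        order = np.argsort(res.p)
        q_sorted = res.q[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)
        assert np.all((res.q >= res.p - 1e-12))

    def test_vectorized_f_matches_scipy(self, rng):
        from scipy.stats import f_oneway

        data, groups = self._data(rng)
        names = sorted(set(groups))
        codes = np.asarray([names.index(g) for g in groups])
        f = stats._group_f(data, codes, 3)
        for node in range(3):
            for m in range(3):
                samples = [data[codes == c, node, m] for c in range(3)]
                assert f[node, m] == pytest.approx(f_oneway(*samples).statistic)
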