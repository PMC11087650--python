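import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nigraquant import (
    ancova_group_effect,
    anova_oneway,
    chi_square_proportion,
    percent_change,
    permutation_corrected_correlations,
    posthoc_ttests,
    roc_auc,
    subgroup_ttest,
)


class TestAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        labels = np.array(["a"] * 18 + ["b"] * 22)
        f, p_f = anova_oneway(x, labels)
        t, p_t = stats.ttest_ind(x[labels == "a"], x[labels == "b"], equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_separated_groups_highly_significant(self):
        x = np.concatenate([np.zeros(10) + 1e-3 * np.arange(10), np.zeros(10), np.full(10, 5.0)])
        labels = np.repeat(["a", "b", "c"], 10)
        _, p = anova_oneway(x, labels)
        assert p < 1e-6

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, p = chi_square_proportion([[10, 10], [20, 20], [5, 5]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_pearson_statistic_on_study_style_counts(self):
        # 16/14, 10/5, 11/11 male/female counts, hand-computed Pearson chi2
        counts = np.array([[16, 14], [10, 5], [11, 11]], float)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        by_hand = float(((counts - expected) ** 2 / expected).sum())
        chi2, p = chi_square_proportion(counts)
        assert chi2 == pytest.approx(by_hand, abs=1e-12)
        assert chi2 == pytest.approx(1.08, abs=0.01)

    def test_fully_separated_two_by_two(self):
        chi2, _ = chi_square_proportion([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_proportion([[0, 0], [5, 5]])


def _ancova_oracle_partial_f(y, labels, age, sex_num):
    """Normal-equations oracle: partial F of the group indicators."""
    levels = sorted(set(labels))
    dummies = np.column_stack([(labels == g).astype(float) for g in levels[1:]])
    x_full = np.column_stack([np.ones(len(y)), dummies, age, sex_num])
    x_red = np.column_stack([np.ones(len(y)), age, sex_num])
    rss = lambda X: float(
        np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    )
    rss_full, rss_red = rss(x_full), rss(x_red)
    df_num = len(levels) - 1
    df_den = len(y) - x_full.shape[1]
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return f, float(stats.f.sf(f, df_num, df_den))


class TestAncova:
    def _toy(self, n_per=3, seed=1):
        rng = np.random.default_rng(seed)
        labels = np.repeat(["HC", "LRRK2", "PD"], n_per)
        age = rng.normal(65, 5, 3 * n_per)
        sex = rng.integers(0, 2, 3 * n_per).astype(float)
        y = rng.normal(0, 1, 3 * n_per) + 0.05 * age + np.repeat([0.0, -0.5, -1.0], n_per)
        return y, labels, age, sex

    def test_matches_normal_equations_oracle_on_small_data(self):
        y, labels, age, sex = self._toy()
        res = ancova_group_effect(y, labels, age, sex)
        f_or, p_or = _ancova_oracle_partial_f(y, labels, age, sex)
        assert res.f_stat == pytest.approx(f_or, abs=1e-8)
        assert res.p_value == pytest.approx(p_or, abs=1e-8)

    def test_covariate_absorbs_measure_tracking_age(self):
        # a measure that is (essentially) the age covariate leaves no group
        # effect once age is controlled
        rng = np.random.default_rng(3)
        labels = np.repeat(["HC", "LRRK2", "PD"], 20)
        age = rng.normal(65, 5, 60)
        sex = rng.integers(0, 2, 60).astype(float)
        y = age + rng.normal(0, 0.01, 60)
        res = ancova_group_effect(y, labels, age, sex)
        assert res.p_value > 0.3
        adj = list(res.adjusted_means.values())
        assert np.ptp(adj) < 0.02

    def test_agrees_with_oneway_anova_when_covariates_carry_nothing(self):
        # with pure-noise covariates the group partial F converges to the
        # one-way ANOVA answer as n grows (df differences vanish)
        rng = np.random.default_rng(4)
        n = 900
        labels = np.repeat(["HC", "LRRK2", "PD"], n // 3)
        y = rng.normal(0, 1, n) + np.repeat([0.0, 0.2, 0.4], n // 3)
        age = rng.normal(65, 5, n)
        sex = rng.integers(0, 2, n).astype(float)
        res = ancova_group_effect(y, labels, age, sex)
        f_anova, _ = anova_oneway(y, labels)
        assert res.f_stat == pytest.approx(f_anova, rel=0.10)

    def test_collinear_design_rejected(self):
        y, labels, age, sex = self._toy()
        with pytest.raises(ValueError, match="rank"):
            ancova_group_effect(y, labels, age, age)  # sex duplicates age

    def test_sex_strings_and_indicators_equivalent(self):
        y, labels, age, sex = self._toy(n_per=5)
        as_str = np.where(sex == 1.0, "M", "F")
        a = ancova_group_effect(y, labels, age, sex)
        b = ancova_group_effect(y, labels, age, as_str)
        assert a.f_stat == pytest.approx(b.f_stat, abs=1e-12)


class TestPosthoc:
    def test_gating_suppresses_all_pairs(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        labels = np.repeat(["HC", "LRRK2", "PD"], 10)
        out = posthoc_ttests(x, labels, gate_p=0.2)
        assert all(np.isnan(v) for v in out.values())

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 5.0, 4.0, 6.0, 7.0])
        sp2 = (3 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 7
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 5))
        p_hand = 2 * stats.t.sf(abs(t), 7)
        x = np.concatenate([a, b])
        labels = np.array(["HC"] * 4 + ["PD"] * 5)
        out = posthoc_ttests(x, labels, gate_p=0.001, pairs=(("HC", "PD"),))
        assert out[("HC", "PD")] == pytest.approx(p_hand, abs=1e-10)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, cmp, expected",
        [
            (394.2, 324.6, -17.7),  # whole-SNc volume, PD vs HC
            (394.2, 359.4, -8.8),   # whole-SNc volume, carriers vs HC
            (74.6, 64.0, -14.2),    # sensorimotor volume, PD vs HC
            (1.51, 1.38, -8.6),
            (100.0, 100.0, 0.0),
        ],
    )
    def test_reported_percentage_changes(self, ref, cmp, expected):
        assert round(percent_change(ref, cmp), 1) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])  # patients score lower
        assert roc_auc(scores, labels, positive_lower=True) == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 1, 4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_direction_flip_complements(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        a = roc_auc(scores, labels, positive_lower=True)
        b = roc_auc(scores, labels, positive_lower=False)
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestPermutationCorrelations:
    def test_perfect_association_attains_smallest_possible_p(self):
        x = np.arange(10, dtype=float)
        scores = pd.DataFrame({"s1": x.copy(), "s2": np.random.default_rng(1).normal(size=10)})
        res = permutation_corrected_correlations(scores, x, n_perm=1000, seed=2)
        by_name = {r.score: r for r in res}
        assert by_name["s1"].r == pytest.approx(1.0)
        assert by_name["s1"].p_fwe == pytest.approx(1 / 1001)
        assert all(r.p_fwe >= 1 / 1001 for r in res if np.isfinite(r.p_fwe))

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        x = np.array([1.0, 3.0, 2.0, 5.0])
        scores = pd.DataFrame({"s1": rng.normal(size=4) + x, "s2": rng.normal(size=4)})
        res = permutation_corrected_correlations(scores, x, seed=0, exact=True)
        # independent enumeration over all 24 orderings of the measure
        mat = scores.to_numpy()
        r_obs = np.array([np.corrcoef(x, mat[:, j])[0, 1] for j in range(2)])
        maxima = []
        for perm in itertools.permutations(range(4)):
            xp = x[list(perm)]
            maxima.append(max(abs(np.corrcoef(xp, mat[:, j])[0, 1]) for j in range(2)))
        maxima = np.array(maxima)
        for j, r in enumerate(res):
            p_oracle = float(np.mean(maxima >= abs(r_obs[j]) - 1e-12))
            assert r.p_fwe == pytest.approx(p_oracle, abs=1e-12)

    def test_p_monotone_nonincreasing_in_observed_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        scores = pd.DataFrame(
            {
                "weak": 0.2 * x + rng.normal(size=20),
                "strong": x + 0.2 * rng.normal(size=20),
            }
        )
        res = {r.score: r for r in permutation_corrected_correlations(scores, x, n_perm=2000, seed=5)}
        assert abs(res["strong"].r) > abs(res["weak"].r)
        assert res["strong"].p_fwe <= res["weak"].p_fwe

    def test_invariant_to_score_relabeling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        scores = pd.DataFrame({"a": rng.normal(size=15), "b": rng.normal(size=15)})
        res1 = {r.score: r.p_fwe for r in permutation_corrected_correlations(scores, x, n_perm=999, seed=7)}
        swapped = scores[["b", "a"]]
        res2 = {r.score: r.p_fwe for r in permutation_corrected_correlations(swapped, x, n_perm=999, seed=7)}
        assert res1["a"] == res2["a"] and res1["b"] == res2["b"]

    def test_constant_score_reported_missing(self):
        x = np.random.default_rng(8).normal(size=12)
        scores = pd.DataFrame({"flat": np.ones(12), "ok": x + 0.1})
        res = {r.score: r for r in permutation_corrected_correlations(scores, x, n_perm=1000, seed=9)}
        assert np.isnan(res["flat"].p_fwe)
        assert np.isfinite(res["ok"].p_fwe)


class TestSubgroupTtest:
    def test_matches_hand_computed_t(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 7)])
        labels = np.array(["G2385R"] * 8 + ["R1628P"] * 7)
        out = subgroup_ttest(pd.DataFrame({"cnr": vals}), labels)
        _, p = stats.ttest_ind(vals[:8], vals[8:], equal_var=True)
        assert out["cnr"] == pytest.approx(p, abs=1e-10)

    def test_study_sized_split_runs(self):
        rng = np.random.default_rng(11)
        labels = np.array(["G2385R"] * 8 + ["R1628P"] * 7)
        df = pd.DataFrame(
            {
                "volume": rng.normal(359, 60, 15),
                "c_vol": rng.normal(0.24, 0.05, 15),
                "cnr": rng.normal(1.38, 0.19, 15),
            }
        )
        out = subgroup_ttest(df, labels)
        assert set(out) == {"volume", "c_vol", "cnr"}
        assert all(0 <= p <= 1 for p in out.values())

    def test_missing_subgroup_rejected(self):
        with pytest.raises(ValueError):
            subgroup_ttest(pd.DataFrame({"cnr": [1.0, 2.0]}), np.array(["G2385R", "G2385R"]))
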