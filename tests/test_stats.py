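import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import oracles
from polytail import (
    adjust_pvalues,
    assess_normality,
    assess_variance_homogeneity,
    call_dpgs,
    cohens_d,
    global_group_test,
    log2_fold_change,
    per_feature_k_group,
    per_feature_two_group,
    run_k_group_test,
    run_two_group_test,
    select_test,
)
from polytail.errors import UndefinedStatisticError, ValidationError
from polytail.stats import assess_groups


class TestAssessNormality:
    def test_constant_values_not_assessable(self):
        assert assess_normality([50, 50, 50]).method == "not_assessable"

    def test_two_observations_not_assessable(self):
        assert assess_normality([1, 2]).method == "not_assessable"

    def test_small_sample_uses_shapiro(self, rng):
        res = assess_normality(rng.normal(70, 20, 100))
        assert res.method == "shapiro"
        stat, p = sps.shapiro(rng.normal(0, 1, 50))
        assert 0 <= res.p <= 1

    def test_large_sample_uses_lilliefors(self, rng):
        res = assess_normality(rng.normal(70, 20, 6000))
        assert res.method == "lilliefors"
        assert res.p > 0.01  # normal data should not be rejected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            assess_normality([1.0, float("nan"), 2.0])


class TestVarianceHomogeneity:
    def test_identical_groups_give_f_zero(self):
        res = assess_variance_homogeneity([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_median_centered_formula(self):
        groups = [[1, 2, 3, 4, 5], [10, 20, 30, 40, 50]]
        res = assess_variance_homogeneity(groups)
        f, p = oracles.levene_median_formula(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_singleton_group_not_assessable(self):
        res = assess_variance_homogeneity([[1, 2, 3], [4, 5, 6], [7]])
        assert not res.assessable


class TestSelectTest:
    """The four canonical routing fixtures of the decision tree."""

    @staticmethod
    def _report(norm_ps, levene_p, min_n=30):
        from polytail.stats import AssumptionReport, HomogeneityResult, NormalityResult
        norms = [NormalityResult("shapiro", 0.9, p) for p in norm_ps]
        homog = (HomogeneityResult(1.0, levene_p) if levene_p is not None
                 else HomogeneityResult(float("nan"), float("nan"), assessable=False))
        return AssumptionReport(norms, homog, min_n)

    @pytest.mark.parametrize("k,expected", [(2, "student_t"), (3, "anova")])
    def test_normal_homogeneous(self, k, expected):
        assert select_test(self._report([0.6] * k, 0.5), k=k) == expected

    @pytest.mark.parametrize("k,expected", [(2, "welch_t"), (3, "welch_anova")])
    def test_normal_heterogeneous(self, k, expected):
        assert select_test(self._report([0.6] * k, 0.01), k=k) == expected

    @pytest.mark.parametrize("k,expected", [(2, "wilcoxon"), (3, "kruskal_wallis")])
    def test_non_normal(self, k, expected):
        assert select_test(self._report([0.6, 0.001] + [0.6] * (k - 2), 0.5), k=k) == expected

    @pytest.mark.parametrize("k,expected", [(2, "wilcoxon"), (3, "kruskal_wallis")])
    def test_small_group_forces_nonparametric(self, k, expected):
        assert select_test(self._report([0.6] * k, 0.5, min_n=2), k=k) == expected

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            select_test(self._report([0.5], None), k=1)


class TestTwoGroupTests:
    def test_wilcoxon_exact_extreme_split(self):
        # all 20 rank splits enumerable by hand; 2 arrangements this extreme
        res = run_two_group_test([1, 2, 3], [4, 5, 6], "wilcoxon")
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_student_t_symmetry(self):
        res = run_two_group_test([1, 2, 3, 4], [1, 2, 3, 4], "student_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        a, b = [10, 12, 14, 16], [11, 13, 15, 17]
        res = run_two_group_test(a, b, "welch_t")
        t, p = oracles.welch_t_formula(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_student_matches_closed_form(self, rng):
        for _ in range(20):
            a = rng.normal(70, 20, rng.integers(3, 40))
            b = rng.normal(75, 25, rng.integers(3, 40))
            res = run_two_group_test(a, b, "student_t")
            t, p = oracles.student_t_formula(a, b)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_variance_both_groups_errors(self):
        with pytest.raises(UndefinedStatisticError):
            run_two_group_test([5, 5, 5], [5, 5, 5], "student_t")

    def test_identical_constant_groups_wilcoxon_p_one(self):
        res = run_two_group_test([5, 5, 5], [5, 5, 5], "wilcoxon")
        assert res.p_value == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_exact_path_equals_enumeration(self, data):
        n1 = data.draw(st.integers(2, 7))
        n2 = data.draw(st.integers(2, 7))
        values = data.draw(st.lists(st.integers(0, 10_000), min_size=n1 + n2,
                                    max_size=n1 + n2, unique=True))
        a, b = values[:n1], values[n1:]
        res = run_two_group_test(a, b, "wilcoxon")
        assert res.p_value == pytest.approx(
            oracles.wilcoxon_exact_enumeration(a, b), abs=1e-12)


class TestKGroupTests:
    def test_identical_groups_kruskal_null(self):
        groups = [[1, 2, 3, 4, 5]] * 3
        res = run_k_group_test(groups, "kruskal_wallis")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert (res.posthoc["p_adjusted"] == 1.0).all()

    def test_kruskal_matches_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = run_k_group_test(groups, "kruskal_wallis")
        h, p = oracles.kruskal_formula(groups)
        # tie-free closed form: 12/(N(N+1)) * sum n_i * Rbar_i^2 - 3(N+1)
        rbar = [2.0, 5.0, 8.0]
        h_hand = 12.0 / (9 * 10) * sum(3 * r**2 for r in rbar) - 3 * 10
        assert h == pytest.approx(h_hand, abs=1e-10)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_anova_matches_f_formula(self, rng):
        groups = [rng.normal(70, 10, 20), rng.normal(72, 10, 20), rng.normal(75, 10, 20)]
        res = run_k_group_test(groups, "anova")
        f, p = oracles.oneway_f_formula(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert len(res.posthoc) == 3

    def test_welch_anova_matches_formula_and_pingouin(self, rng):
        groups = [rng.normal(70, 5, 15), rng.normal(75, 15, 25), rng.normal(80, 30, 35)]
        res = run_k_group_test(groups, "welch_anova")
        f, p = oracles.welch_anova_formula(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [15, 25, 35]),
        })
        table = pg.welch_anova(data=df, dv="y", between="g")
        assert res.p_value == pytest.approx(float(table["p_unc"].iloc[0]), rel=1e-8)

    def test_games_howell_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = [rng.normal(70, 5, 12), rng.normal(75, 20, 18), rng.normal(85, 40, 24)]
        res = run_k_group_test(groups, "welch_anova", labels=["a", "b", "c"])
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [12, 18, 24]),
        })
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        got = res.posthoc.sort_values("pair").reset_index(drop=True)
        ref_p = ref.assign(pair=ref["A"] + "-" + ref["B"]).sort_values("pair")
        np.testing.assert_allclose(got["p_adjusted"].to_numpy(),
                                   ref_p["pval"].to_numpy(), atol=1e-8)

    def test_dunn_matches_hand_calculation(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2, 5, 8; N=9, no ties
        res = run_k_group_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]], "kruskal_wallis",
                               labels=["a", "b", "c"])
        base_var = 9 * 10 / 12.0
        se = math.sqrt(base_var * (2 / 3))
        z_ab = (2 - 5) / se
        p_ab = min(1.0, 3 * 2 * sps.norm.sf(abs(z_ab)))
        row = res.posthoc.set_index("pair").loc["a-b"]
        assert row["statistic"] == pytest.approx(z_ab, abs=1e-10)
        assert row["p_adjusted"] == pytest.approx(p_ab, abs=1e-10)

    def test_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            run_k_group_test([[1, 2], [3, 4]], "anova")


class TestEffectSizes:
    def test_cohens_d_unit_pooled_sd(self):
        assert cohens_d([4, 5, 6], [1, 2, 3]) == pytest.approx(3.0)

    def test_cohens_d_identity_and_scale_invariance(self, rng):
        a = rng.normal(70, 10, 20)
        assert cohens_d(a, a) == pytest.approx(0.0)
        b = rng.normal(60, 15, 25)
        assert cohens_d(3 * a, 3 * b) == pytest.approx(cohens_d(a, b), rel=1e-10)

    def test_log2fc_directions(self):
        assert log2_fold_change(50, 100) == pytest.approx(1.0)
        assert log2_fold_change(80, 80) == pytest.approx(0.0)
        assert log2_fold_change(100, 50) == pytest.approx(-1.0)
        with pytest.raises(ValidationError):
            log2_fold_change(0, 50)


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "BH")
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.4], "bonferroni"),
                                   [0.02, 0.8])
        assert adjust_pvalues([0.9, 0.9], "bonferroni").max() == 1.0

    def test_single_p_unchanged(self):
        for method in ("holm", "BH", "bonferroni", "hochberg", "BY"):
            assert adjust_pvalues([0.04], method)[0] == pytest.approx(0.04)

    def test_missing_values_excluded_from_m(self):
        out = adjust_pvalues([0.01, np.nan, 0.04], "bonferroni")
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.08])

    def test_fdr_is_alias_of_bh(self, rng):
        p = rng.uniform(size=30)
        np.testing.assert_allclose(adjust_pvalues(p, "fdr"), adjust_pvalues(p, "BH"))

    @pytest.mark.parametrize("method,oracle", [
        ("holm", oracles.holm_adjust),
        ("hochberg", oracles.hochberg_adjust),
        ("bonferroni", oracles.bonferroni_adjust),
        ("BH", oracles.bh_adjust),
        ("BY", oracles.by_adjust),
    ])
    def test_matches_stepwise_oracle(self, method, oracle, rng):
        for _ in range(25):
            p = rng.uniform(size=int(rng.integers(1, 40))).tolist()
            np.testing.assert_allclose(adjust_pvalues(p, method), oracle(p),
                                       atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_adjusted_at_least_raw_and_order_preserved(self, p):
        for method in ("holm", "BH", "bonferroni"):
            out = adjust_pvalues(p, method)
            assert np.all(out >= np.asarray(p) - 1e-15)
            assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.2], "BH")


def _two_group_table(rng, n_genes=5, n=40, shift=0.0, affected=()):
    rows = []
    rid = 0
    for g in range(n_genes):
        gene = f"g{g}"
        for group, delta in (("CTR", 0.0), ("HIGH", shift if gene in affected else 0.0)):
            for v in rng.normal(70 + delta, 10, n):
                rid += 1
                rows.append((f"r{rid}", f"t{g}", max(1, round(v)), f"{group}1",
                             group, gene))
    return pd.DataFrame(rows, columns=["read_id", "transcript_id", "polyA_length",
                                       "sample_name", "group", "gene_id"])


class TestPerFeatureTwoGroup:
    def test_planted_shift_detected_with_expected_sign(self, rng):
        table = _two_group_table(rng, shift=30.0, affected=("g0",), n=50)
        stats = per_feature_two_group(table, control_group="CTR",
                                      treated_group="HIGH")
        row = stats.set_index("feature_id").loc["g0"]
        assert row["p_value"] < 0.05
        assert row["log2fc"] > 0  # treated longer
        assert row["dpg_call"] == "expansion"

    def test_identical_groups_are_null(self):
        values = [50, 60, 70, 80]
        rows = [(f"r{i}", "t0", v, "s", grp, "g0")
                for i, (grp, v) in enumerate(
                    [(g, v) for g in ("CTR", "HIGH") for v in values])]
        table = pd.DataFrame(rows, columns=["read_id", "transcript_id",
                                            "polyA_length", "sample_name",
                                            "group", "gene_id"])
        stats = per_feature_two_group(table, mode="wilcoxon_only")
        row = stats.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["cohens_d"] == pytest.approx(0.0)
        assert row["log2fc"] == pytest.approx(0.0)
        assert row["dpg_call"] == "ns"

    def test_adaptive_small_group_routes_to_wilcoxon(self, rng):
        table = _two_group_table(rng, n_genes=1, n=10)
        # keep only two control reads for g0
        ctr = table[table["group"] == "CTR"].head(2)
        table = pd.concat([ctr, table[table["group"] == "HIGH"]])
        stats = per_feature_two_group(table, mode="adaptive", min_n=2)
        assert stats.iloc[0]["test_id"] == "wilcoxon"

    def test_below_min_n_not_tested(self, rng):
        table = _two_group_table(rng, n_genes=1, n=2)
        stats = per_feature_two_group(table, min_n=3)
        assert stats.iloc[0]["dpg_call"] == "not_tested"
        assert np.isnan(stats.iloc[0]["p_value"])

    def test_unknown_group_label_rejected(self, rng):
        with pytest.raises(ValidationError, match="LOW"):
            per_feature_two_group(_two_group_table(rng), treated_group="LOW")

    def test_wilcoxon_only_and_adaptive_share_feature_set(self, rng):
        table = _two_group_table(rng, n_genes=4)
        s1 = per_feature_two_group(table, mode="wilcoxon_only")
        s2 = per_feature_two_group(table, mode="adaptive")
        assert list(s1["feature_id"]) == list(s2["feature_id"])
        assert (s1["test_id"] == "wilcoxon").all()


def _k_group_table(rng, n_genes=3, n=40, shifts=None):
    shifts = shifts or {}
    rows = []
    rid = 0
    for g in range(n_genes):
        gene = f"g{g}"
        for group in ("CTR", "LOW", "HIGH"):
            delta = shifts.get((gene, group), 0.0)
            for v in rng.normal(70 + delta, 10, n):
                rid += 1
                rows.append((f"r{rid}", f"t{g}", max(1, round(v)),
                             f"{group}1", group, gene))
    return pd.DataFrame(rows, columns=["read_id", "transcript_id", "polyA_length",
                                       "sample_name", "group", "gene_id"])


class TestPerFeatureKGroup:
    def test_identical_distributions_null(self):
        values = list(range(50, 90))
        rows = [(f"r{g}{i}", "t0", v, "s", g, "g0")
                for g in ("CTR", "LOW", "HIGH") for i, v in enumerate(values)]
        table = pd.DataFrame(rows, columns=["read_id", "transcript_id",
                                            "polyA_length", "sample_name",
                                            "group", "gene_id"])
        stats, posthoc = per_feature_k_group(table, mode="kruskal_only")
        assert stats.iloc[0]["p_value"] == pytest.approx(1.0)
        assert stats.iloc[0]["dpg_call"] == "ns"

    def test_planted_shift_recovered(self, rng):
        table = _k_group_table(rng, n_genes=4, n=50,
                               shifts={("g0", "HIGH"): 40.0})
        stats, posthoc = per_feature_k_group(table, mode="adaptive")
        row = stats.set_index("feature_id").loc["g0"]
        assert row["padj"] < 0.05
        assert row["dpg_call"] == "dpg"
        assert set(posthoc["feature_id"]) == set(stats["feature_id"])

    def test_mode_contrast_on_normal_data(self, rng):
        table = _k_group_table(rng, n_genes=2, n=30)
        s_k, _ = per_feature_k_group(table, mode="kruskal_only")
        s_a, _ = per_feature_k_group(table, mode="adaptive")
        assert (s_k["test_id"] == "kruskal_wallis").all()
        assert set(s_a["test_id"]) <= {"anova", "welch_anova"}
        assert list(s_k["feature_id"]) == list(s_a["feature_id"])

    def test_two_groups_directed_to_two_group_runner(self, rng):
        table = _two_group_table(rng)
        with pytest.raises(ValidationError):
            per_feature_k_group(table)


class TestCallDpgs:
    @pytest.mark.parametrize("padj,log2fc,expected", [
        (0.049, -0.3, "collapsed"),
        (0.049, 0.3, "expansion"),
        (0.05, -0.3, "ns"),      # the alpha comparison is strict
        (0.2, 1.0, "ns"),
        (np.nan, np.nan, "not_tested"),
    ])
    def test_threshold_and_direction(self, padj, log2fc, expected):
        table = pd.DataFrame({"feature_id": ["f"], "padj": [padj],
                              "log2fc": [log2fc], "dpg_call": ["ns"]})
        assert call_dpgs(table).iloc[0]["dpg_call"] == expected

    def test_direction_free_label_without_log2fc(self):
        table = pd.DataFrame({"feature_id": ["f"], "padj": [0.01],
                              "dpg_call": ["ns"]})
        assert call_dpgs(table).iloc[0]["dpg_call"] == "dpg"


class TestGlobalGroupTest:
    def test_three_skewed_groups_select_kruskal(self, rng):
        rows = []
        for group, mean in (("CTR", 90), ("LOW", 80), ("HIGH", 70)):
            sigma2 = np.log1p((25 / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            draws = np.maximum(np.rint(rng.lognormal(mu, np.sqrt(sigma2), 2000)), 1)
            rows += [(f"{group}{i}", "t", int(v), f"{group}1", group)
                     for i, v in enumerate(draws)]
        table = pd.DataFrame(rows, columns=["read_id", "transcript_id",
                                            "polyA_length", "sample_name", "group"])
        res = global_group_test(table)
        assert res.test_id == "kruskal_wallis"
        assert res.p_value < 1e-3
        assert (res.posthoc["p_adjusted"] < 0.05).all()

    def test_constant_identical_groups_degenerate(self):
        rows = [(f"r{g}{i}", "t", 50, "s", g)
                for g in ("A", "B") for i in range(5)]
        table = pd.DataFrame(rows, columns=["read_id", "transcript_id",
                                            "polyA_length", "sample_name", "group"])
        res = global_group_test(table)
        assert res.test_id == "wilcoxon"
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self, tiny_polya):
        with pytest.raises(ValidationError):
            global_group_test(tiny_polya[tiny_polya["group"] == "CTR"])
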