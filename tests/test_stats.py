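import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from restmmn.datatypes import BANDS, CohortResultTable, ValidationError
from restmmn.stats import (
    GroupSummary,
    bonferroni_adjust,
    chi_squared,
    cochran_cox_t,
    gg_epsilon,
    kruskal_wallis,
    one_way_anova,
    pooled_t,
    rm_anova_gg,
    run_group_analysis,
    spearman,
)


class TestPooledT:
    def test_printed_panss_positive_summaries(self):
        """Published summary fixture: 15.80 +/- 2.83 (n=15) vs 13.73 +/- 2.90
        (n=11) gives t = 1.824."""
        res = pooled_t(
            GroupSummary("a", 15, 15.80, 2.83), GroupSummary("b", 11, 13.73, 2.90)
        )
        assert res.value == pytest.approx(1.824, abs=5e-4)
        assert res.df == 24

    def test_identical_summaries_give_zero(self):
        s = GroupSummary("a", 10, 5.0, 1.0)
        assert pooled_t(s, s).value == 0.0

    def test_unit_sd_hand_value(self):
        res = pooled_t(GroupSummary("a", 10, 1.0, 1.0), GroupSummary("b", 10, 0.0, 1.0))
        assert res.value == pytest.approx(1.0 / np.sqrt(2.0 / 10.0), abs=1e-4)

    def test_matches_scipy_on_raw_data(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=9) + 0.5
        res = pooled_t(GroupSummary.from_sample("x", x), GroupSummary.from_sample("y", y))
        ref = ss.ttest_ind(x, y, equal_var=True)
        assert res.value == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValidationError):
            pooled_t(GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 0.0))


class TestCochranCox:
    def test_equal_variance_equal_n_equals_pooled_t(self):
        a, b = GroupSummary("a", 10, 1.3, 2.0), GroupSummary("b", 10, 0.2, 2.0)
        assert cochran_cox_t(a, b).value == pytest.approx(pooled_t(a, b).value)

    def test_unit_example(self):
        res = cochran_cox_t(GroupSummary("a", 10, 1.0, 1.0), GroupSummary("b", 10, 0.0, 1.0))
        assert res.value == pytest.approx(2.2361, abs=1e-4)

    def test_one_sample_limit_when_b_degenerate(self):
        res = cochran_cox_t(GroupSummary("a", 9, 2.0, 1.5), GroupSummary("b", 8, 1.0, 0.0))
        assert res.value == pytest.approx((2.0 - 1.0) / (1.5 / np.sqrt(9)))

    def test_p_consistent_with_critical_value(self):
        a, b = GroupSummary("a", 15, 5.33, 1.11), GroupSummary("b", 15, 1.18, 0.40)
        res = cochran_cox_t(a, b)
        assert res.extra["significant_at_alpha"]
        assert res.p < 0.001

    def test_welch_option_matches_scipy(self, rng):
        x, y = rng.normal(size=10), rng.normal(scale=3.0, size=14) + 1.0
        res = cochran_cox_t(
            GroupSummary.from_sample("x", x), GroupSummary.from_sample("y", y), welch_df=True
        )
        ref = ss.ttest_ind(x, y, equal_var=False)
        assert res.value == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_both_variances_zero_errors(self):
        with pytest.raises(ValidationError):
            cochran_cox_t(GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 0.0))


class TestOneWayAnova:
    def test_summary_path_equals_raw_path(self, rng):
        groups = [rng.normal(size=n) + d for n, d in [(8, 0.0), (10, 0.4), (7, -0.2)]]
        raw = one_way_anova(groups)
        summ = one_way_anova([GroupSummary.from_sample(str(i), g) for i, g in enumerate(groups)])
        assert raw.value == pytest.approx(summ.value)
        assert raw.p == pytest.approx(summ.p)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(size=9), rng.normal(size=9) + 1.0, rng.normal(size=9)]
        res = one_way_anova(groups)
        ref = ss.f_oneway(*groups)
        assert res.value == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_hand_built_sums_of_squares(self):
        # groups with means 1, 2, 3 (n=5 each), within-SS = 4 per group
        g = [np.array([0, 1, 1, 1, 2]) + d for d in (0, 1, 2)]
        # SSB = 5*((1-2)^2+(0)^2+(1)^2) = 10, MSB = 5; SSW = 2*3... compute:
        # each group var: values d,d+1,d+1,d+1,d+2 -> SS = 2; SSW = 6, MSW = 6/12 = 0.5
        res = one_way_anova(g)
        assert res.value == pytest.approx((10 / 2) / (6 / 12))
        assert res.df == (2, 12)

    def test_degenerate_identical_constants(self):
        res = one_way_anova([np.ones(4), np.ones(4)])
        assert res.value == 0.0 and res.extra.get("degenerate")


class TestRmAnovaGG:
    def test_two_levels_epsilon_is_one(self, rng):
        X = rng.normal(size=(12, 2))
        grp = ["a"] * 6 + ["b"] * 6
        res = rm_anova_gg(X, grp)
        assert res["within"].extra["epsilon"] == pytest.approx(1.0)

    def test_matches_pingouin_mixed_anova(self, rng):
        """Independent oracle: pingouin's mixed ANOVA reproduces the same
        F statistics and uncorrected p-values; epsilon agrees with
        pingouin's estimator applied to group-centered data."""
        import pingouin as pg

        X = rng.normal(size=(18, 4)) + rng.normal(size=(18, 1)) * 0.6
        grp = np.repeat(["a", "b", "c"], 6)
        mine = rm_anova_gg(X, grp)

        rows = []
        for i in range(18):
            for j in range(4):
                rows.append({"subj": f"s{i}", "grp": grp[i], "band": f"b{j}", "score": X[i, j]})
        ref = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="score", within="band",
            between="grp", subject="subj", correction=True,
        ).set_index("Source")
        assert mine["group"].value == pytest.approx(ref.loc["grp", "F"])
        assert mine["within"].value == pytest.approx(ref.loc["band", "F"])
        assert mine["interaction"].value == pytest.approx(ref.loc["Interaction", "F"])
        assert mine["within"].extra["uncorrected_p"] == pytest.approx(ref.loc["band", "p_unc"])

        Xc = X - np.vstack([X[grp == g].mean(axis=0) for g in grp])
        eps_ref = pg.epsilon(pd.DataFrame(Xc), correction="gg")
        assert mine["within"].extra["epsilon"] == pytest.approx(eps_ref)

    def test_compound_symmetric_data_epsilon_near_one(self):
        eps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5)) + rng.normal(size=(60, 1))
            grp = np.repeat(["a", "b", "c"], 20)
            eps.append(rm_anova_gg(X, grp)["within"].extra["epsilon"])
        assert np.mean(eps) > 0.9

    def test_missing_cells_rejected(self):
        X = np.ones((6, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            rm_anova_gg(X, ["a"] * 3 + ["b"] * 3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_epsilon_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        A = rng.normal(size=(k + 3, k))
        S = A.T @ A
        eps = gg_epsilon(S)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.02], m=3), [0.03, 0.06])
        np.testing.assert_allclose(bonferroni_adjust([0.5], m=3), [1.0])
        np.testing.assert_allclose(
            bonferroni_adjust([0.017, 0.033, 0.2]), [0.051, 0.099, 0.6]
        )

    def test_never_decreases_and_caps(self):
        p = np.linspace(0.0, 1.0, 11)
        adj = bonferroni_adjust(p, m=11)
        assert (adj >= p).all() and adj.max() <= 1.0

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([1.2])


class TestChiSquared:
    def test_printed_gender_table(self):
        """Published fixture: [[10,11,10],[5,4,5]] gives X^2 = 0.207, df=2."""
        res = chi_squared([[10, 11, 10], [5, 4, 5]])
        assert res.value == pytest.approx(0.207, abs=5e-4)
        assert res.df == 2

    def test_independent_table_is_zero(self):
        res = chi_squared([[10, 20, 30], [1, 2, 3]])
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2_hand_value(self):
        assert chi_squared([[5, 0], [0, 5]]).value == pytest.approx(10.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared([[0, 0], [1, 2]])


class TestKruskalWallis:
    def test_fully_separated_hand_ranks(self):
        # ranks 1..6 -> H = 12/(6*7) * (2^2+ ... ) hand computation = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.value == pytest.approx(12 / 42 * (4.5 + 24.5 + 60.5) - 21)

    def test_all_identical_values(self):
        res = kruskal_wallis([[2, 2], [2, 2]])
        assert res.value == 0.0 and res.extra.get("all_tied")

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).value == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).value == pytest.approx(-1.0)

    def test_ties_averaged_hand_value(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rx, ry = [1.0, 2.5, 2.5, 4.0], [1.0, 3.0, 2.0, 4.0]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).value == pytest.approx(expected)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


def _cohort_table(rng, n=6, with_effect=True):
    rows = []
    for g, amp in [("AVH", 3.0), ("NonAVH", 4.5), ("HC", 4.5)]:
        for i in range(n):
            a = amp + rng.normal(scale=0.5)
            lat = 180 + rng.normal(scale=5.0)
            for band in BANDS:
                c = (0.8 if (g == "AVH" and with_effect) else 0.6) + rng.normal(scale=0.05)
                rows.append(
                    dict(subject_id=f"{g}{i}", group=g, band=band,
                         C=c, L=2.0 - c, mmn_latency_ms=lat, mmn_amplitude_uv=max(a, 0.0))
                )
    return CohortResultTable(pd.DataFrame(rows))


class TestRunGroupAnalysis:
    def test_report_structure_complete(self, rng):
        rep = run_group_analysis(_cohort_table(rng))
        tests = rep["tests"]
        for key in ("rm_anova_C", "rm_anova_L", "anova_mmn_amplitude_uv",
                    "posthoc_mmn_amplitude_uv", "spearman_avh"):
            assert key in tests
        assert len(tests["posthoc_mmn_amplitude_uv"]) == 3
        for pair in tests["posthoc_mmn_amplitude_uv"].values():
            assert pair["p_bonferroni"] >= pair["p"]

    def test_single_band_reduces_to_one_way(self, rng):
        table = _cohort_table(rng)
        df = table.frame[table.frame["band"] == "alpha"].reset_index(drop=True)
        rep = run_group_analysis(CohortResultTable(df))
        assert set(rep["tests"]["rm_anova_C"]) == {"group"}

    def test_report_files_written(self, rng, tmp_path):
        run_group_analysis(_cohort_table(rng), out_dir=tmp_path)
        assert (tmp_path / "stats_report.json").exists()
        assert (tmp_path / "stats_report.csv").exists()
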