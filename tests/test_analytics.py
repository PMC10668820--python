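"""Descriptives, correlation, quartile grouping, ANOVA + SNK, normality."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pigqsc.analytics import (
    GROUP_LABELS,
    assign_quartile_groups,
    check_normality,
    compare_groups,
    correlation_table,
    describe,
    one_way_anova,
    pearson_with_p,
    snk_posthoc,
    stars_for_p,
)
from pigqsc.errors import ContractError, DegenerateInputError


# ---------------------------------------------------------------------------
# descriptives


class TestDescribe:
    def test_odd_n_median(self):
        df = pd.DataFrame({"x": np.arange(1, 24)})
        row = describe(df, ["x"]).loc["x"]
        assert row["p50"] == 12.0
        assert row["mean"] == 12.0
        assert row["sd"] == pytest.approx(np.std(np.arange(1, 24), ddof=1))

    def test_constant_column(self):
        df = pd.DataFrame({"x": [4.2] * 10})
        row = describe(df, ["x"]).loc["x"]
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert row["min"] == row["max"] == row["p25"] == row["p50"] == row["p75"] == 4.2

    @pytest.mark.parametrize("method,expected", [
        # hand-computed for x = (2.80, 4.20, 5.60, 8.40), n=4:
        # haverage (SPSS weighted average): position (n+1)p
        #   p25 -> 1.25 -> 2.80 + 0.25*1.40 = 3.15
        #   p50 -> 2.50 -> 4.20 + 0.50*1.40 = 4.90
        #   p75 -> 3.75 -> 5.60 + 0.75*2.80 = 7.70
        ("haverage", (3.15, 4.90, 7.70)),
        # linear interpolation: position 1 + (n-1)p
        #   p25 -> 1.75 -> 2.80 + 0.75*1.40 = 3.85
        #   p75 -> 3.25 -> 4.20 + ... wait p50 -> 2.5 -> 4.90; p75 -> 3.25
        #   p75 -> 5.60 + 0.25*2.80 = 6.30
        ("linear", (3.85, 4.90, 6.30)),
    ])
    def test_both_percentile_definitions_against_hand_oracle(self, method, expected):
        df = pd.DataFrame({"x": [2.80, 4.20, 5.60, 8.40]})
        row = describe(df, ["x"], percentile_method=method).loc["x"]
        assert (row["p25"], row["p50"], row["p75"]) == pytest.approx(expected)

    def test_quantile_ordering_invariant(self, small_cohort_frame):
        table = describe(small_cohort_frame)
        for _, row in table.iterrows():
            assert (row["min"] <= row["p25"] <= row["p50"]
                    <= row["p75"] <= row["max"])

    def test_unknown_variable_rejected(self, small_cohort_frame):
        with pytest.raises(ContractError, match="nope"):
            describe(small_cohort_frame, ["nope"])


# ---------------------------------------------------------------------------
# correlation


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        cell = pearson_with_p(x, 2 * x + 1)
        assert cell.r == pytest.approx(1.0)
        assert cell.stars == "***"

    def test_orthogonalized_residuals_give_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        assert abs(pearson_with_p(x, resid).r) < 1e-12

    def test_six_point_hand_dataset_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0, 8.0])
        cell = pearson_with_p(x, y)
        # brute-force product-moment computation
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / math.sqrt(np.sum((x - x.mean()) ** 2)
                                * np.sum((y - y.mean()) ** 2)))
        assert cell.r == pytest.approx(r_direct, abs=1e-12)
        # two-tailed p via the t transform on n-2 df
        t = r_direct * math.sqrt((6 - 2) / (1 - r_direct ** 2))
        assert cell.p == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-9)

    def test_constant_input_is_degenerate_not_nan(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999),
           a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        r_xy = pearson_with_p(x, y).r
        assert pearson_with_p(y, x).r == pytest.approx(r_xy, abs=1e-12)
        assert pearson_with_p(a * x + b, y).r == pytest.approx(r_xy, abs=1e-9)

    @pytest.mark.parametrize("p,expected", [
        (0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
        (0.03, "*"), (0.05, "*"), (0.0501, ""), (0.5, ""),
    ])
    def test_star_thresholds_inclusive_at_boundaries(self, p, expected):
        assert stars_for_p(p) == expected


class TestCorrelationTable:
    def test_eleven_by_eight_layout(self, small_cohort_frame):
        table = correlation_table(small_cohort_frame)
        assert table.r.shape == (11, 8)
        assert list(table.r.index)[-1] == "overall"
        assert table.stars.shape == (11, 8)

    def test_degenerate_cells_flagged_table_still_returned(self, small_cohort_frame):
        df = small_cohort_frame.copy()
        df["fcr"] = 1.76  # constant KPI
        table = correlation_table(df)
        assert all(col == "fcr" for _, col in table.degenerate)
        assert len(table.degenerate) == 11
        assert np.isnan(table.r["fcr"]).all()
        assert np.isfinite(table.r["pwsy"]).all()

    def test_text_rendering_carries_stars(self, large_cohort_frame):
        table = correlation_table(large_cohort_frame)
        text = table.to_text_frame()
        assert "***" in text.loc["overall", "pwsy"]


# ---------------------------------------------------------------------------
# quartile grouping


class TestQuartiles:
    def _frame(self, values):
        return pd.DataFrame({"farm_id": [f"f{i:03d}" for i in range(len(values))],
                             "pwsy": values})

    def test_n8_distinct_gives_2_4_2(self):
        g = assign_quartile_groups(self._frame(np.arange(8.0)), "pwsy")
        assert g.sizes == {"Q1": 2, "Q2Q3": 4, "Q4": 2}

    def test_n23_gives_6_11_6(self):
        g = assign_quartile_groups(self._frame(np.arange(23.0)), "pwsy")
        assert g.sizes == {"Q1": 6, "Q2Q3": 11, "Q4": 6}

    def test_direction_high_takes_highest_into_q1(self):
        values = [10.0, 30.0, 20.0, 40.0, 5.0, 25.0, 15.0, 35.0]
        g = assign_quartile_groups(self._frame(values), "pwsy", direction="high")
        assert set(g.farms("Q1")) == {"f003", "f007"}  # 40 and 35
        assert set(g.farms("Q4")) == {"f004", "f000"}  # 5 and 10

    def test_reversing_direction_swaps_extremes(self):
        values = list(np.random.default_rng(2).normal(size=16))
        hi = assign_quartile_groups(self._frame(values), "pwsy", "high")
        lo = assign_quartile_groups(self._frame(values), "pwsy", "low")
        assert set(hi.farms("Q1")) == set(lo.farms("Q4"))
        assert set(hi.farms("Q4")) == set(lo.farms("Q1"))
        assert set(hi.farms("Q2Q3")) == set(lo.farms("Q2Q3"))

    def test_too_few_farms_rejected(self):
        with pytest.raises(ContractError, match="n >= 4"):
            assign_quartile_groups(self._frame([1.0, 2.0, 3.0]), "pwsy")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(4, 60), seed=st.integers(0, 999))
    def test_groups_always_partition_with_specified_sizes(self, n, seed):
        values = np.random.default_rng(seed).normal(size=n)
        g = assign_quartile_groups(self._frame(values), "pwsy")
        n_extreme = math.floor(n / 4 + 0.5)
        assert g.sizes["Q1"] == g.sizes["Q4"] == n_extreme
        assert sum(g.sizes.values()) == n
        assert set(g.membership.unique()) <= set(GROUP_LABELS)


# ---------------------------------------------------------------------------
# ANOVA


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        f, p = one_way_anova([g, g, g])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 14)
        f, p = one_way_anova([a, b])
        t, tp = stats.ttest_ind(a, b)  # pooled-variance t
        assert f == pytest.approx(t ** 2, abs=1e-9)
        assert p == pytest.approx(tp, abs=1e-12)

    def test_hand_computed_three_by_three(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
        # grand mean 4; group means 2,3,7; SSB = 3*(4+1+9)=42, dfb=2
        # SSW = 2+2+2=6, dfw=6 -> F = 21/1 = 21
        f, p = one_way_anova(groups)
        assert f == pytest.approx(21.0, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(21.0, 2, 6), rel=1e-12)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.3, n) for m, n in ((0, 5), (1, 8), (0.5, 6))]
        f, p = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_within_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])


# ---------------------------------------------------------------------------
# SNK


class TestSNK:
    def test_identical_means_share_a_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 6)
        res = snk_posthoc([base, base + 0.01, base - 0.01])
        assert res.letters == ["a", "a", "a"]
        assert not res.significant_pairs

    def test_two_groups_match_pooled_t_decision(self):
        # q = sqrt(2)*|t| for k=2, so SNK and the pooled t-test must agree
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 7)
            b = rng.normal(rng.uniform(0, 1.5), 1, 7)
            res = snk_posthoc([a, b], alpha=0.05)
            _, tp = stats.ttest_ind(a, b)
            assert res.different(0, 1) == (tp < 0.05), f"seed {seed}"

    def test_three_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 8.0, 16.0)]
        res = snk_posthoc(groups)
        assert res.letters == ["c", "b", "a"]  # highest mean gets 'a'
        assert len(res.significant_pairs) == 3

    def test_middle_overlap_produces_shared_letters(self):
        # construct means far/near so only the extreme pair separates
        rng = np.random.default_rng(12)
        found = False
        for seed in range(60):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(m, 2.0, 5) for m in (0.0, 2.0, 4.0)]
            res = snk_posthoc(groups)
            letters = set("".join(res.letters))
            if len(res.significant_pairs) == 1 and len(letters) == 2:
                found = True
                # the middle group shares a letter with both extremes
                mid = sorted(range(3), key=lambda i: np.mean(groups[i]))[1]
                assert len(res.letters[mid]) == 2
                break
        assert found, "no partially-overlapping instance found in 60 seeds"

    def test_tukey_significant_implies_snk_significant(self):
        # SNK critical values q(alpha, p<=k) never exceed Tukey's q(alpha, k),
        # so every Tukey rejection must also be an SNK rejection
        for seed in range(25):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(m, 1.5, 6) for m in (0.0, 1.0, 2.5, 3.0)]
            res = snk_posthoc(groups, alpha=0.05)
            tukey = stats.tukey_hsd(*groups)
            for i in range(4):
                for j in range(i + 1, 4):
                    if tukey.pvalue[i, j] < 0.05:
                        assert res.different(i, j), f"seed {seed}, pair {(i, j)}"

    def test_extreme_pair_decision_equals_tukey_on_widest_span(self):
        # at span k the SNK and Tukey criteria coincide
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            groups = [rng.normal(m, 1.5, 6) for m in (0.0, 0.8, 1.6)]
            res = snk_posthoc(groups, alpha=0.05)
            means = [np.mean(g) for g in groups]
            lo, hi = int(np.argmin(means)), int(np.argmax(means))
            tukey = stats.tukey_hsd(*groups)
            assert res.different(lo, hi) == (tukey.pvalue[lo, hi] < 0.05)

    def test_familywise_error_under_complete_null(self):
        """SNK complete-null FWER stays near alpha (5000 seeded reps, k=3)."""
        rng = np.random.default_rng(2024)
        k, n, reps, alpha = 3, 6, 5000, 0.05
        data = rng.standard_normal((reps, k, n))
        rejections = sum(
            bool(snk_posthoc(list(data[rep]), alpha=alpha).significant_pairs)
            for rep in range(reps))
        fwer = rejections / reps
        assert fwer <= alpha + 0.015

    def test_snk_matches_independent_null_range_logic(self):
        """Under a complete null, an SNK rejection must coincide with the
        widest-span studentized-range test exceeding q(alpha, k, dfw)."""
        rng = np.random.default_rng(77)
        q3 = stats.studentized_range.ppf(0.95, 3, 15)
        for _ in range(200):
            groups = rng.standard_normal((3, 6))
            res = snk_posthoc(list(groups), alpha=0.05)
            means = groups.mean(axis=1)
            msw = groups.var(axis=1, ddof=1).mean()
            se = math.sqrt(msw / 6)
            any_sig = (means.max() - means.min()) / se >= q3
            assert bool(res.significant_pairs) == bool(any_sig)


# ---------------------------------------------------------------------------
# normality + group tables


class TestNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(9).normal(size=200)
        _, p = check_normality(x)
        assert p > 0.05

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(10).exponential(size=50)
        _, p = check_normality(x)
        assert p < 0.05

    def test_constant_vector_is_contract_error(self):
        with pytest.raises(ContractError):
            check_normality([3.0] * 10)


class TestCompareGroups:
    def test_quartile_table_shape_and_letters(self, small_cohort_frame):
        grouping = assign_quartile_groups(small_cohort_frame, "pwsy", "high")
        rows = compare_groups(small_cohort_frame, grouping,
                              ["pwsy", "overall",
                               "medication_cost_eur_per_piglet"])
        assert [r.variable for r in rows] == ["pwsy", "overall",
                                              "medication_cost_eur_per_piglet"]
        for r in rows:
            assert set(r.letters) == set(GROUP_LABELS)
            assert sum(r.group_ns.values()) == 23
        # the ranking variable itself must separate Q1 from Q4
        pwsy_row = rows[0]
        assert not set(pwsy_row.letters["Q1"]) & set(pwsy_row.letters["Q4"])
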