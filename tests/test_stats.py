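"""Trait statistics: cohort join, ANOVA/Tukey, chi-squared prevalence."""

import numpy as np
import pandas as pd
import pytest

from reefcore.stats import (
    build_cohort,
    one_way_anova,
    prevalence_test,
    report_to_frame,
    reproduce_report,
    tukey_hsd,
)


def hand_anova(groups):
    """Sums-of-squares one-way F, written out longhand."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def hand_chi2(table, correction=False):
    """Textbook Pearson X2 = sum (O - E)^2 / E with optional Yates."""
    obs = np.asarray(table, dtype=float)
    expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    return float((diff**2 / expected).sum())


class TestOneWayAnova:
    def test_equal_means_f_near_zero(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = one_way_anova(values, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_toy_data_matches_hand_computation(self):
        data = {"a": [2.0, 4.0], "b": [6.0, 8.0], "c": [10.0, 12.0]}
        values = sum(data.values(), [])
        groups = sum(([k] * 2 for k in data), [])
        res = one_way_anova(values, groups)
        assert res.statistic == pytest.approx(hand_anova(list(data.values())))
        assert res.df == (2, 3)

    def test_random_data_matches_hand_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups_data = [rng.normal(rng.normal(), 1, rng.integers(3, 10)) for _ in range(k)]
            values = np.concatenate(groups_data)
            labels = np.concatenate([[f"g{i}"] * len(g) for i, g in enumerate(groups_data)])
            res = one_way_anova(values, labels)
            assert res.statistic == pytest.approx(hand_anova(groups_data), rel=1e-10)

    def test_single_value_group_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = one_way_anova([1.0, 2.0, 3.0, 4.0, 9.0], ["a", "a", "b", "b", "c"])
        assert set(res.group_sizes) == {"a", "b"}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestTukeyHsd:
    def test_identical_groups_p_near_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        out = tukey_hsd(values, groups)
        assert float(out["p_adj"].iloc[0]) > 0.95

    def test_only_outlying_group_flagged(self, rng):
        a = rng.normal(0, 0.5, 12)
        b = rng.normal(0.1, 0.5, 12)
        c = rng.normal(8, 0.5, 12)
        values = np.concatenate([a, b, c])
        groups = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        out = tukey_hsd(values, groups)
        sig = {(r["a"], r["b"]): bool(r["significant"]) for _, r in out.iterrows()}
        assert sig[("a", "c")] and sig[("b", "c")]
        assert not sig[("a", "b")]

    def test_matches_studentized_range_by_hand(self):
        from scipy.stats import studentized_range

        data = {"a": [2.0, 4.0, 3.0], "b": [6.0, 8.0, 7.0], "c": [5.0, 5.5, 6.5]}
        values = sum(data.values(), [])
        groups = sum(([k] * 3 for k in data), [])
        out = tukey_hsd(values, groups)
        # hand computation for pair (a, b), equal n
        mse = np.mean([np.var(v, ddof=1) for v in data.values()])
        q = abs(np.mean(data["b"]) - np.mean(data["a"])) / np.sqrt(mse / 3)
        p_hand = studentized_range.sf(q, k=3, df=6)
        row = out[(out["a"] == "a") & (out["b"] == "b")]
        assert float(row["p_adj"].iloc[0]) == pytest.approx(p_hand, abs=1e-4)


class TestPrevalenceTest:
    def test_equal_prevalence_zero_statistic(self):
        flags = pd.Series([True, False] * 10)
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        res = prevalence_test(flags, groups, yates_2x2=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_matches_hand_with_and_without_correction(self):
        # table [[20, 10], [5, 25]]
        flags = pd.Series([True] * 20 + [False] * 10 + [True] * 5 + [False] * 25)
        groups = pd.Series(["a"] * 30 + ["b"] * 30)
        with_c = prevalence_test(flags, groups, yates_2x2=True)
        without_c = prevalence_test(flags, groups, yates_2x2=False)
        table = [[20, 10], [5, 25]]
        assert with_c.statistic == pytest.approx(hand_chi2(table, correction=True))
        assert without_c.statistic == pytest.approx(hand_chi2(table, correction=False))
        assert with_c.df == 1

    def test_random_kx2_tables_match_textbook_formula(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            table = rng.integers(1, 30, size=(k, 2))
            flags, groups = [], []
            for gi in range(k):
                flags += [True] * table[gi, 0] + [False] * table[gi, 1]
                groups += [f"g{gi}"] * int(table[gi].sum())
            res = prevalence_test(pd.Series(flags), pd.Series(groups), yates_2x2=False)
            assert res.statistic == pytest.approx(hand_chi2(table), rel=1e-10)
            assert res.df == k - 1

    def test_prevalence_invariant_to_row_order(self, rng):
        flags = pd.Series(rng.random(40) < 0.4)
        groups = pd.Series(rng.choice(["x", "y"], 40))
        a = prevalence_test(flags, groups)
        perm = rng.permutation(40)
        b = prevalence_test(flags.iloc[perm].reset_index(drop=True),
                            groups.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_all_absent_table_returns_zero(self):
        flags = pd.Series([False] * 12)
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        res = prevalence_test(flags, groups)
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestBuildCohort:
    def test_joins_all_components(self):
        assign = pd.Series(["DB", "LB"], index=["c1", "c2"])
        cores = pd.DataFrame(
            {"mean_density_g_cm3": [1.2, 1.1], "habitat": ["outer reef", "Rock Island"]},
            index=["c1", "c2"],
        )
        flags = pd.DataFrame({"stress_1998": [True, False]}, index=["c1", "c2"])
        cohort = build_cohort(assign, cores, flags)
        assert cohort.loc["c1", "lineage"] == "DB"
        assert cohort.loc["c2", "stress_1998"] == False  # noqa: E712

    def test_missing_core_carried_with_nan(self):
        assign = pd.Series(["DB", "LB"], index=["c1", "c2"])
        cores = pd.DataFrame({"mean_density_g_cm3": [1.2]}, index=["c1"])
        cohort = build_cohort(assign, cores)
        assert np.isnan(cohort.loc["c2", "mean_density_g_cm3"])

    def test_duplicate_ids_rejected(self):
        assign = pd.Series(["DB", "LB"], index=["c1", "c1"])
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort(assign, pd.DataFrame(index=pd.Index([], name="id")))

    def test_disjoint_ids_warn(self):
        assign = pd.Series(["DB"], index=["c1"])
        cores = pd.DataFrame({"mean_density_g_cm3": [1.0]}, index=["c9"])
        with pytest.warns(UserWarning, match="no overlapping"):
            build_cohort(assign, cores)


def synthetic_cohort(rng, n_per=20, density_shift=None, prev=None):
    lineages = ["DB", "LB", "PI", "RD"]
    density_shift = density_shift or {k: 0.0 for k in lineages}
    prev = prev or {k: 0.3 for k in lineages}
    rows = []
    for lin in lineages:
        for i in range(n_per):
            d = 1.2 + density_shift[lin] + rng.normal(0, 0.1)
            e = 1.0 + rng.normal(0, 0.15)
            rows.append(
                {
                    "id": f"{lin}{i}",
                    "lineage": lin,
                    "habitat": "Rock Island" if rng.random() < 0.5 else "outer reef",
                    "mean_density_g_cm3": d,
                    "mean_extension_cm": e,
                    "mean_calcification_g_cm2_yr": d * e,
                    "stress_1998": bool(rng.random() < prev[lin]),
                    "stress_2010": bool(rng.random() < prev[lin] / 2),
                }
            )
    return pd.DataFrame(rows).set_index("id")


class TestReproduceReport:
    def test_effect_cohort_recovers_injected_ordering(self, rng):
        cohort = synthetic_cohort(
            rng, n_per=40,
            density_shift={"DB": 0.0, "LB": 0.0, "PI": -0.05, "RD": -0.3},
            prev={"DB": 0.68, "LB": 0.22, "PI": 0.17, "RD": 0.25},
        )
        report = reproduce_report(cohort)
        prev = report["lineage_prevalence_1998"].table["prevalence"]
        assert prev.idxmax() == "DB"
        means = cohort.groupby("lineage")["mean_density_g_cm3"].mean()
        assert means.idxmin() == "RD"
        assert report["lineage_anova_density"].p_value < 0.001
        frame = report_to_frame(report)
        assert {"lineage_anova_density", "lineage_prevalence_1998"} <= set(frame["test"])

    def test_admixed_rows_excluded_from_tests(self, rng):
        cohort = synthetic_cohort(rng, n_per=10)
        cohort.loc[cohort.index[0], "lineage"] = "admixed"
        report = reproduce_report(cohort)
        assert sum(report["lineage_anova_density"].group_sizes.values()) == 39

    def test_missing_columns_named(self, rng):
        cohort = synthetic_cohort(rng).drop(columns=["mean_extension_cm"])
        with pytest.raises(ValueError, match="mean_extension_cm"):
            reproduce_report(cohort)

    def test_type_i_error_calibrated_under_null(self, rng):
        """Null-effect cohorts reject at ~alpha for both ANOVA and chi-squared."""
        n_rep, alpha = 400, 0.05
        rej_f = rej_x = 0
        for _ in range(n_rep):
            values = rng.normal(size=40)
            groups = np.repeat(list("abcd"), 10)
            if one_way_anova(values, groups).p_value < alpha:
                rej_f += 1
            flags = pd.Series(rng.random(60) < 0.4)
            glab = pd.Series(np.repeat(list("abc"), 20))
            if prevalence_test(flags, glab).p_value < alpha:
                rej_x += 1
        # 3 sigma of binomial(400, 0.05) is ~0.033
        assert rej_f / n_rep == pytest.approx(alpha, abs=0.035)
        assert rej_x / n_rep <= alpha + 0.035  # chi2 is conservative at small n
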