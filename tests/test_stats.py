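"""Statistical tests, bootstrap CIs and star mapping."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import neuritequant as nq
from neuritequant import StatsParams
from neuritequant.errors import InputError, StatisticsError
from neuritequant.stats import (
    anova_vs_control,
    bootstrap_median_ci,
    compare_conditions,
    one_sample_t,
    one_way_anova,
    p_to_stars,
    two_sample_t,
)


class TestOneSampleT:
    def test_symmetric_sample_gives_t0_p1(self):
        t, df, p = one_sample_t([0.9, 1.0, 1.1], 1.0)
        assert t == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula_and_scipy(self):
        values, mu0 = [1.2, 1.5, 1.4, 1.3], 1.0
        t, df, p = one_sample_t(values, mu0)
        # hand-evaluated: mean 1.35, s = sqrt(0.05/3), t = 0.35/(s/2)
        s = (0.05 / 3) ** 0.5
        assert t == pytest.approx(0.35 / (s / 2), rel=1e-12)
        assert t == pytest.approx(5.42218, rel=1e-5)
        ref = sps.ttest_1samp(values, mu0)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatisticsError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)  # zero variance
        with pytest.raises(StatisticsError):
            one_sample_t([1.0], 0.0)  # n < 2


class TestTwoSampleT:
    def test_identical_groups_give_t0_p1(self):
        t, _, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_matches_scipy_including_df(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 17)
        t, df, p = two_sample_t(a, b, equal_var=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == pytest.approx(ref.df, rel=1e-12)

    def test_pooled_matches_scipy(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 1, 9)
        t, df, p = two_sample_t(a, b, equal_var=True)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == 15

    def test_p_decreases_monotonically_with_shift(self):
        base = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        ps = [two_sample_t(base, base + delta)[2] for delta in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] < 1e-4


class TestAnova:
    def test_identical_groups_give_f0_p1(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3]] * 3)
        assert f == pytest.approx(0.0)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # SS_between = 6, SS_within = 6 -> F = (6/2)/(6/6) = 3.0
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        f, df1, df2, p = one_way_anova(groups)
        assert f == pytest.approx(3.0, rel=1e-12)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_member_group_rejected(self):
        with pytest.raises(StatisticsError):
            one_way_anova([[1, 2, 3], [4]])

    def test_vs_control_bonferroni(self, rng):
        groups = {
            "ctrl": rng.normal(0, 1, 10),
            "a": rng.normal(1, 1, 10),
            "b": rng.normal(0, 1, 10),
        }
        rows = anova_vs_control(groups, "ctrl")
        assert [r[0] for r in rows] == ["a", "b"]
        for _, t, df, p_raw, p_adj in rows:
            assert df == 27
            assert p_adj >= p_raw
            assert p_adj <= 1.0
            assert p_adj == pytest.approx(min(1.0, 2 * p_raw))


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_median_ci([5, 5, 5, 5, 5], n_boot=1000, seed=1)
        assert (lo, hi) == (5.0, 5.0)

    def test_same_seed_reproduces_interval(self, rng):
        x = rng.normal(size=30)
        assert bootstrap_median_ci(x, 2000, seed=9) == bootstrap_median_ci(x, 2000, seed=9)

    def test_interval_brackets_sample_median(self, rng):
        x = rng.normal(size=50)
        lo, hi = bootstrap_median_ci(x, 2000, seed=2)
        assert lo <= np.median(x) <= hi

    def test_preconditions(self):
        with pytest.raises(StatisticsError):
            bootstrap_median_ci([1, 2], 1000, seed=0)  # n < 3
        with pytest.raises(StatisticsError):
            bootstrap_median_ci([1, 2, 3], 500, seed=0)  # n_boot < 1000


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.02, "*"),
            (0.00005, "****"),
            (0.2, "ns"),
            (0.05, "ns"),  # thresholds are strict inequalities
            (0.01, "*"),
            (0.001, "**"),
            (0.0001, "***"),
            (0.0, "****"),
            (1.0, "ns"),
        ],
    )
    def test_threshold_map(self, p, expected):
        assert p_to_stars(p) == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InputError):
            p_to_stars(bad)


class TestCompareConditions:
    def _metrics(self, rng, shift=0.0):
        rows = []
        for cond, mu in (("control", 10.0), ("treated", 10.0 + shift)):
            for i in range(12):
                rows.append(
                    dict(
                        field_id=f"{cond}_{i}",
                        condition=cond,
                        neurite_length_per_cell_um=rng.normal(mu, 1.0),
                        excluded=False,
                    )
                )
        return pd.DataFrame(rows)

    def test_two_groups_table_shape_and_stars(self, rng):
        table = compare_conditions(self._metrics(rng, shift=5.0), "neurite_length_per_cell_um")
        assert len(table) == 2
        assert set(table["group"]) == {"control", "treated"}
        assert (table["ci_lo"] <= table["median"]).all()
        assert (table["median"] <= table["ci_hi"]).all()
        row = table[table["group"] == "treated"].iloc[0]
        assert row["p"] < 0.001
        assert row["stars"] in ("***", "****")

    def test_excluded_fields_dropped(self, rng):
        df = self._metrics(rng)
        df.loc[0, "excluded"] = True
        table = compare_conditions(df, "neurite_length_per_cell_um")
        assert table[table["group"] == "control"].iloc[0]["n"] == 11

    def test_three_groups_uses_anova_and_control_rows(self, rng):
        df = self._metrics(rng, shift=3.0)
        extra = df[df["condition"] == "control"].copy()
        extra["condition"] = "other"
        extra["field_id"] = extra["field_id"] + "_o"
        df = pd.concat([df, extra], ignore_index=True)
        table = compare_conditions(
            df, "neurite_length_per_cell_um", StatsParams(control="control")
        )
        assert len(table) == 3
        assert (table[table["group"] == "control"]["test"] == "one_way_anova").all()
        assert (
            table[table["group"] != "control"]["test"] == "t_vs_control_bonferroni"
        ).all()

    def test_single_condition_rejected(self, rng):
        df = self._metrics(rng)
        with pytest.raises(StatisticsError):
            compare_conditions(df[df["condition"] == "control"], "neurite_length_per_cell_um")
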