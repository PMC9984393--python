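"""Group-comparison statistics: t-test, split-plot ANOVA, permutation test."""

import math
from itertools import combinations

import numpy as np
import pytest

from somnokit import (
    DesignMatrix,
    mixed_anova,
    permutation_group_test,
    unpaired_t_test,
)


def pooled_t_oracle(x, y):
    """Textbook pooled-variance t statistic, written independently."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    s1 = sum((v - m1) ** 2 for v in x)
    s2 = sum((v - m2) ** 2 for v in y)
    sp2 = (s1 + s2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestUnpairedT:
    def test_identical_samples(self):
        r = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_textbook_example(self):
        # {1,2,3} vs {4,5,6}: pooled sd = 1, se = sqrt(2/3)
        r = unpaired_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.t == pytest.approx(-3.6742, abs=1e-4)
        assert r.df == 4

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 2, size=int(rng.integers(2, 12)))
            y = rng.normal(1, 3, size=int(rng.integers(2, 12)))
            r = unpaired_t_test(x, y)
            assert r.t == pytest.approx(pooled_t_oracle(list(x), list(y)), abs=1e-10)
            assert r.df == len(x) + len(y) - 2

    def test_one_sided_mode(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        two = unpaired_t_test(x, y)
        less = unpaired_t_test(x, y, alternative="less")
        assert less.p == pytest.approx(two.p / 2)

    def test_welch_differs_under_unequal_variance(self, rng):
        x = rng.normal(0, 0.1, size=8)
        y = rng.normal(0, 10.0, size=4)
        student = unpaired_t_test(x, y)
        welch = unpaired_t_test(x, y, welch=True)
        assert welch.df < student.df

    def test_degenerate_constant_samples(self):
        with pytest.raises(ValueError, match="degenerate"):
            unpaired_t_test([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError, match="two observations"):
            unpaired_t_test([1.0], [2.0, 3.0])


def ss_oracle(values, groups):
    """Brute-force split-plot sums of squares via per-observation loops."""
    n, t = values.shape
    labels = sorted(set(groups))
    grand = values.mean()
    g_mean = {g: values[groups == g].mean() for g in labels}
    s_mean = values.mean(axis=1)
    t_mean = values.mean(axis=0)
    cell = {
        (g, j): values[groups == g][:, j].mean() for g in labels for j in range(t)
    }
    ss = dict.fromkeys(["group", "subj", "time", "int", "err", "total"], 0.0)
    for i in range(n):
        g = groups[i]
        for j in range(t):
            y = values[i, j]
            ss["total"] += (y - grand) ** 2
            ss["group"] += (g_mean[g] - grand) ** 2
            ss["subj"] += (s_mean[i] - g_mean[g]) ** 2
            ss["time"] += (t_mean[j] - grand) ** 2
            ss["int"] += (cell[(g, j)] - g_mean[g] - t_mean[j] + grand) ** 2
            ss["err"] += (y - cell[(g, j)] - s_mean[i] + g_mean[g]) ** 2
    n_g = len(labels)
    df = {
        "group": (n_g - 1, n - n_g),
        "time": (t - 1, (n - n_g) * (t - 1)),
        "int": ((n_g - 1) * (t - 1), (n - n_g) * (t - 1)),
    }
    f = {
        "group": (ss["group"] / df["group"][0]) / (ss["subj"] / df["group"][1]),
        "time": (ss["time"] / df["time"][0]) / (ss["err"] / df["time"][1]),
        "int": (ss["int"] / df["int"][0]) / (ss["err"] / df["int"][1]),
    }
    return ss, f


class TestMixedAnova:
    def test_constant_identical_groups_have_zero_f(self):
        values = np.full((6, 4), 5.0)
        d = DesignMatrix(values, np.repeat(["a", "b"], 3))
        res = mixed_anova(d)
        assert res.F_group == 0.0
        assert res.F_interaction == 0.0

    def test_hand_constructed_design_matches_oracle(self):
        values = np.array(
            [
                [3.0, 5.0],
                [4.0, 6.0],
                [2.0, 5.0],
                [7.0, 9.0],
                [8.0, 12.0],
                [6.0, 10.0],
            ]
        )
        groups = np.repeat(["ctl", "mor"], 3)
        res = mixed_anova(DesignMatrix(values, groups))
        _, f = ss_oracle(values, groups)
        assert res.F_group == pytest.approx(f["group"], rel=1e-12)
        assert res.F_time == pytest.approx(f["time"], rel=1e-12)
        assert res.F_interaction == pytest.approx(f["int"], rel=1e-12)

    def test_random_designs_match_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, size=2)
            t = int(rng.integers(2, 9))
            values = rng.normal(10, 3, size=(n1 + n2, t))
            groups = np.repeat(["a", "b"], [n1, n2])
            res = mixed_anova(DesignMatrix(values, groups))
            ss, f = ss_oracle(values, groups)
            for key, got in (
                ("group", res.F_group),
                ("time", res.F_time),
                ("int", res.F_interaction),
            ):
                assert got == pytest.approx(f[key], rel=1e-8)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        values = rng.normal(0, 1, size=(9, 5))
        values[5:] += 1.5
        groups = np.repeat(["a", "b"], [5, 4])
        res = mixed_anova(DesignMatrix(values, groups))
        tidy = pd.DataFrame(
            {
                "y": values.ravel(),
                "subject": np.repeat(np.arange(9), 5),
                "group": np.repeat(groups, 5),
                "time": np.tile(np.arange(5), 9),
            }
        )
        pg_res = pg.mixed_anova(
            data=tidy, dv="y", within="time", subject="subject", between="group"
        ).set_index("Source")
        assert res.F_group == pytest.approx(pg_res.loc["group", "F"], rel=1e-6)
        assert res.F_time == pytest.approx(pg_res.loc["time", "F"], rel=1e-6)
        assert res.F_interaction == pytest.approx(
            pg_res.loc["Interaction", "F"], rel=1e-6
        )
        assert res.p_group == pytest.approx(pg_res.loc["group", "p_unc"], rel=1e-6)

    def test_ss_components_sum_to_total(self, rng):
        values = rng.normal(0, 5, size=(8, 6))
        d = DesignMatrix(values, np.repeat(["a", "b"], 4))
        res = mixed_anova(d)
        parts = sum(v for k, v in res.ss.items() if k != "total")
        assert parts == pytest.approx(res.ss["total"], rel=1e-10)

    def test_shift_and_scale_invariance(self, rng):
        values = rng.normal(0, 2, size=(7, 4))
        groups = np.repeat(["a", "b"], [3, 4])
        base = mixed_anova(DesignMatrix(values, groups))
        shifted = mixed_anova(DesignMatrix(values + 100.0, groups))
        scaled = mixed_anova(DesignMatrix(values * 3.0, groups))
        for res in (shifted, scaled):
            assert res.F_group == pytest.approx(base.F_group, rel=1e-8)
            assert res.p_interaction == pytest.approx(base.p_interaction, rel=1e-8)
        assert scaled.ss["total"] == pytest.approx(9.0 * base.ss["total"], rel=1e-10)

    def test_paper_shaped_design_df(self, rng):
        # 13 animals in two unequal groups, 8 hourly time points:
        # group df (1, 11), within df (7, 77)
        values = rng.normal(30, 5, size=(13, 8))
        res = mixed_anova(DesignMatrix(values, np.repeat(["a", "b"], [6, 7])))
        assert res.df_group == (1, 11)
        assert res.df_time == (7, 77)
        assert res.df_interaction == (7, 77)

    def test_missing_cells_rejected(self):
        values = np.ones((4, 3))
        values[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            DesignMatrix(values, np.repeat(["a", "b"], 2))

    def test_single_animal_group_rejected(self):
        with pytest.raises(ValueError, match="two animals"):
            DesignMatrix(np.ones((3, 2)), np.array(["a", "a", "b"]))

    def test_gg_correction_shrinks_df(self, rng):
        values = rng.normal(0, 1, size=(10, 6))
        values[:, 0] += rng.normal(0, 3, size=10)  # break sphericity
        d = DesignMatrix(values, np.repeat(["a", "b"], 5))
        plain = mixed_anova(d)
        gg = mixed_anova(d, correction="gg")
        assert gg.df_time[0] < plain.df_time[0]
        assert gg.F_time == pytest.approx(plain.F_time)

    def test_from_tidy_round_trip(self, rng):
        import pandas as pd

        values = rng.normal(0, 1, size=(4, 3))
        tidy = pd.DataFrame(
            {
                "minutes": values.ravel(),
                "animal_id": np.repeat(["m1", "m2", "m3", "m4"], 3),
                "condition": np.repeat(["ctl", "ctl", "mor", "mor"], 3),
                "hour": np.tile([0, 1, 2], 4),
            }
        )
        d = DesignMatrix.from_tidy(
            tidy, value="minutes", subject="animal_id", group="condition", time="hour"
        )
        np.testing.assert_allclose(d.values, values)


def exhaustive_oracle(values, groups, stat):
    """Enumerate all relabelings with fixed group sizes via combinations."""
    labels = sorted(set(groups))
    n1 = int(np.sum(groups == labels[0]))
    n = len(groups)
    obs = stat(values, groups)
    stats = []
    for idx in combinations(range(n), n1):
        lab = np.array([labels[0] if i in idx else labels[1] for i in range(n)])
        stats.append(stat(values, lab))
    return sum(s >= obs - 1e-12 for s in stats) / len(stats)


class TestPermutation:
    def test_huge_group_difference_gives_minimal_p(self, rng):
        values = rng.normal(0, 1, size=(12, 4))
        values[6:] += 1000.0
        d = DesignMatrix(values, np.repeat(["a", "b"], 6))
        res = permutation_group_test(d, n_perm=199, seed=1)
        # C(12,6) = 924 > 199 -> sampled mode; observed stat is maximal
        assert not res.exhaustive
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_three_vs_three_exhaustive_matches_enumeration_oracle(self, rng):
        values = rng.normal(0, 1, size=(6, 3))
        values[3:] += 1.0
        groups = np.repeat(["a", "b"], 3)
        d = DesignMatrix(values, groups)
        res = permutation_group_test(d, n_perm=999, seed=0)
        assert res.exhaustive and res.n_perm == 20

        def stat(v, g):
            return mixed_anova(DesignMatrix(v, g)).F_group

        assert res.p_value == pytest.approx(exhaustive_oracle(values, groups, stat))

    def test_mean_diff_statistic(self, rng):
        values = rng.normal(0, 1, size=(6, 2))
        d = DesignMatrix(values, np.repeat(["a", "b"], 3))
        res = permutation_group_test(d, statistic="mean_diff", n_perm=999, seed=0)
        labels = np.unique(d.groups)
        expected = abs(
            values[d.groups == labels[0]].mean() - values[d.groups == labels[1]].mean()
        )
        assert res.observed == pytest.approx(expected)

    def test_max_t_reports_per_time_adjusted_p(self, rng):
        values = rng.normal(0, 1, size=(8, 5))
        values[4:, 2] += 50.0  # effect at one time point only
        d = DesignMatrix(values, np.repeat(["a", "b"], 4))
        res = permutation_group_test(d, statistic="max_t", n_perm=200, seed=3)
        assert res.per_time_p is not None and res.per_time_p.shape == (5,)
        assert res.per_time_p[2] == res.per_time_p.min()
        # family-wise adjusted p-values are at least the p of the maximum
        assert (res.per_time_p >= res.p_value - 1e-12).all()

    def test_n_perm_floor(self, rng):
        d = DesignMatrix(rng.normal(size=(4, 2)), np.repeat(["a", "b"], 2))
        with pytest.raises(ValueError, match="99"):
            permutation_group_test(d, n_perm=10)
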