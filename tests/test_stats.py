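"""One-way/two-way ANOVA, Newman–Keuls step-down and Bonferroni posthoc."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import swimquant as sq
from swimquant.errors import DesignError


def oneway_ss_oracle(groups):
    """Independent sum-of-squares computation of the one-way F statistic."""
    arrays = [np.asarray(v, float) for v in groups.values()]
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb = len(arrays) - 1
    dfw = len(allv) - len(arrays)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        groups = {g: [1.0, 2.0, 3.0] for g in "abc"}
        res = sq.one_way_anova(groups)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_f_is_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        res = sq.one_way_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_sum_of_squares_oracle(self, rng):
        groups = {g: rng.normal(i, 1.5, 12) for i, g in enumerate("abc")}
        res = sq.one_way_anova(groups)
        f, p = oneway_ss_oracle(groups)
        assert res.F == pytest.approx(f, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_group_descriptives(self):
        res = sq.one_way_anova({"a": [1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        assert res.group_means["a"] == 2.0
        assert res.group_ns == {"a": 2, "b": 3}
        assert res.group_sems["b"] == pytest.approx(2.0 / np.sqrt(3))

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            sq.one_way_anova({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(DesignError):
            sq.one_way_anova({"a": [1.0, 2.0]})


class TestNewmanKeuls:
    def test_global_null_finds_nothing(self, rng):
        groups = {g: rng.normal(0, 1, 10) for g in "abcd"}
        nk = sq.newman_keuls(groups, alpha=1e-6)
        assert not nk.table["significant"].any()

    def test_two_groups_reduce_to_pooled_t_decision(self, rng):
        for shift in (0.0, 0.5, 2.0):
            a, b = rng.normal(0, 1, 12), rng.normal(shift, 1, 12)
            nk = sq.newman_keuls({"a": a, "b": b}, alpha=0.05)
            t_sig = sps.ttest_ind(a, b).pvalue < 0.05
            assert nk.table["significant"].iloc[0] == t_sig

    def test_four_group_fixture_against_hand_computation(self):
        """Decisions checked pair-by-pair against explicitly computed
        studentized-range tests on a fixed, well-separated fixture."""
        rng = np.random.default_rng(3)
        means = {"d0": 0.0, "d1": 0.3, "d2": 3.0, "d3": 6.0}
        groups = {g: m + rng.normal(0, 1, 12) for g, m in means.items()}
        nk = sq.newman_keuls(groups, alpha=0.05)
        res = sq.one_way_anova(groups)
        order = sorted(groups, key=lambda g: np.mean(groups[g]))
        dfw = res.df_within
        msw = res.ms_within

        def q_of(g1, g2):
            return abs(np.mean(groups[g2]) - np.mean(groups[g1])) / np.sqrt(
                msw / 12)

        # widest range (span 4) must be rejected on this fixture
        assert q_of(order[0], order[3]) > sps.studentized_range.ppf(0.95, 4, dfw)
        tab = nk.table.set_index(["group1", "group2"])
        assert tab.loc[(order[0], order[3]), "significant"]
        # the two span-3 ranges
        for pair, span in [((order[0], order[2]), 3),
                           ((order[1], order[3]), 3)]:
            expect = q_of(*pair) > sps.studentized_range.ppf(0.95, span, dfw)
            assert tab.loc[pair, "significant"] == expect
        # adjacent pair of the two near-identical dose groups: not significant
        near = tuple(sorted(("d0", "d1"), key=lambda g: np.mean(groups[g])))
        assert not tab.loc[near, "significant"]

    def test_step_down_coherence_exhaustive(self):
        """No pair inside a non-rejected enclosing range is ever declared
        significant, across an exhaustive sweep of mean patterns."""
        rng = np.random.default_rng(11)
        noise = [rng.normal(0, 1, 8) for _ in range(4)]
        for pattern in itertools.product([0.0, 1.0, 2.5], repeat=4):
            groups = {f"g{i}": pattern[i] + noise[i] for i in range(4)}
            if sq.one_way_anova(groups).ms_within == 0:
                continue
            nk = sq.newman_keuls(groups, alpha=0.05)
            order = sorted(groups, key=lambda g: np.mean(groups[g]))
            pos = {g: i for i, g in enumerate(order)}
            tab = nk.table.set_index(["group1", "group2"])
            for (g1, g2), row in tab.iterrows():
                if not row["significant"]:
                    continue
                i, j = pos[g1], pos[g2]
                for a in range(0, i + 1):
                    for b in range(j, 4):
                        if (a, b) == (i, j):
                            continue
                        assert tab.loc[(order[a], order[b]), "significant"], (
                            "significant sub-range inside retained range")

    def test_rejects_superset_of_tukey(self, rng):
        """NK uses smaller range parameters for sub-ranges, so on balanced
        data it rejects every pair Tukey's HSD rejects."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for seed in range(5):
            r = np.random.default_rng(seed)
            data = np.concatenate(
                [r.normal(m, 1, 10) for m in (0.0, 0.5, 1.5, 3.0)])
            labels = np.repeat(list("abcd"), 10)
            tukey = pairwise_tukeyhsd(data, labels, alpha=0.05)
            groups = {g: data[labels == g] for g in "abcd"}
            nk_pairs = set(map(frozenset,
                               sq.newman_keuls(groups).significant_pairs()))
            for (g1, g2), rej in zip(
                    itertools.combinations("abcd", 2), tukey.reject):
                if rej:
                    assert frozenset((g1, g2)) in nk_pairs

    def test_zero_within_variance_is_degenerate(self):
        with pytest.raises(DesignError):
            sq.newman_keuls({"a": [1.0, 1.0], "b": [2.0, 2.0]})


def balanced_frame(cell_means, n, sd, rng):
    rows = []
    for (tp, grp), mu in cell_means.items():
        for v in rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu):
            rows.append({"time_point": tp, "group": grp, "value": v})
    return pd.DataFrame(rows)


def twoway_ss_oracle(df):
    """Balanced two-way ANOVA with interaction via explicit sums of squares."""
    y = df["value"].to_numpy()
    grand = y.mean()
    a_levels = df["time_point"].unique()
    b_levels = df["group"].unique()
    n = len(df) / (len(a_levels) * len(b_levels))
    ss_a = sum(
        len(df[df["time_point"] == a]) *
        (df.loc[df["time_point"] == a, "value"].mean() - grand) ** 2
        for a in a_levels)
    ss_b = sum(
        len(df[df["group"] == b]) *
        (df.loc[df["group"] == b, "value"].mean() - grand) ** 2
        for b in b_levels)
    ss_cells = 0.0
    ss_e = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = df[(df["time_point"] == a) & (df["group"] == b)]["value"]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(a_levels) * len(b_levels)
    ms_e = ss_e / df_e
    return {
        "time_point": (ss_a / df_a) / ms_e,
        "group": (ss_b / df_b) / ms_e,
        "time_point:group": (ss_ab / df_ab) / ms_e,
    }


class TestTwoWayAnova:
    def test_constructed_effects(self, rng):
        cell_means = {(tp, g): float(tp) for tp in range(4)
                      for g in ("control", "treated")}
        df = balanced_frame(cell_means, n=6, sd=0.01, rng=rng)
        res = sq.two_way_anova(df, "value")
        tab = res.table.set_index("effect")
        assert tab.loc["time_point", "p"] < 1e-30
        assert tab.loc["group", "F"] < 5.0  # no treatment effect built in
        assert tab.loc["group", "p"] > 0.001

    def test_factor_swap_symmetry(self, rng):
        cell_means = {(tp, g): tp + (2.0 if g == "treated" else 0.0)
                      for tp in range(3) for g in ("control", "treated")}
        df = balanced_frame(cell_means, n=5, sd=1.0, rng=rng)
        res = sq.two_way_anova(df, "value", factor_a="time_point",
                               factor_b="group")
        swapped = sq.two_way_anova(df, "value", factor_a="group",
                                   factor_b="time_point")
        a = res.table.set_index("effect")
        b = swapped.table.set_index("effect")
        assert a.loc["time_point", "F"] == pytest.approx(
            b.loc["time_point", "F"], rel=1e-9)
        assert a.loc["group", "F"] == pytest.approx(
            b.loc["group", "F"], rel=1e-9)

    def test_matches_sum_of_squares_oracle(self, rng):
        cell_means = {(tp, g): rng.normal(0, 2) for tp in range(4)
                      for g in ("control", "treated")}
        df = balanced_frame(cell_means, n=12, sd=1.0, rng=rng)
        res = sq.two_way_anova(df, "value")
        expected = twoway_ss_oracle(df)
        tab = res.table.set_index("effect")
        for effect, f in expected.items():
            assert tab.loc[effect, "F"] == pytest.approx(f, abs=1e-9)

    def test_empty_cell_rejected(self, rng):
        df = balanced_frame({(0, "control"): 0.0, (0, "treated"): 1.0,
                             (1, "control"): 0.0}, n=4, sd=1.0, rng=rng)
        with pytest.raises(DesignError, match="incomplete"):
            sq.two_way_anova(df, "value")

    def test_unbalanced_rejected(self, rng):
        df = balanced_frame({(tp, g): 0.0 for tp in range(2)
                             for g in ("control", "treated")},
                            n=4, sd=1.0, rng=rng)
        df = df.drop(index=[0])
        with pytest.raises(DesignError, match="unbalanced"):
            sq.two_way_anova(df, "value")


class TestBonferroni:
    def test_single_comparison_unadjusted(self, rng):
        cell_means = {(0, "control"): 0.0, (0, "treated"): 1.0}
        df = balanced_frame(cell_means, n=12, sd=1.0, rng=rng)
        res = sq.bonferroni_vs_control(df, "value", control_label="control")
        row = res.table.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"])

    def test_multiplication_rule(self):
        # 4 time points: adjusted p = raw p x 4, so raw 0.02 -> 0.08 (ns)
        rng = np.random.default_rng(0)
        cell_means = {(tp, g): 0.0 for tp in range(4)
                      for g in ("control", "treated")}
        df = balanced_frame(cell_means, n=12, sd=1.0, rng=rng)
        res = sq.bonferroni_vs_control(df, "value", control_label="control")
        tab = res.table
        for _, row in tab.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 4))
            if 0.0125 <= row["p_raw"] < 0.05:
                assert not row["significant"]

    def test_adjusted_never_below_raw(self, rng):
        cell_means = {(tp, g): rng.normal(0, 1) for tp in range(3)
                      for g in ("control", "treated", "high_dose")}
        df = balanced_frame(cell_means, n=6, sd=1.0, rng=rng)
        res = sq.bonferroni_vs_control(df, "value", control_label="control")
        assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-15).all()

    def test_missing_control_cell_rejected(self, rng):
        df = balanced_frame({(0, "treated"): 0.0, (1, "treated"): 0.0,
                             (0, "other"): 0.0, (1, "other"): 0.0},
                            n=4, sd=1.0, rng=rng)
        with pytest.raises(DesignError):
            sq.bonferroni_vs_control(df, "value", control_label="control")


def test_asterisks():
    assert sq.stats.asterisks(0.01) == "*"
    assert sq.stats.asterisks(0.05) == ""
    assert sq.stats.asterisks(0.2) == ""
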