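"""Bootstrap, rank tests, shift summary, chi-squared, and ANOVA layers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from labelbias import (
    BootstrapConfig,
    bootstrap_statistic,
    chi_squared_test,
    item_shift_summary,
    mixed_anova,
    oneway_anova,
    rank_sum_item_test,
    repeated_measures_anova,
    signed_rank_test,
)

from conftest import make_records


# ---------------------------------------------------------------------------
# bootstrap


def _survey(n_volunteers, rng, spread=True):
    frames = []
    for i in range(n_volunteers):
        offset = rng.integers(-1, 2) if spread else 0
        same = np.clip(np.array([2, 1, 0, 2]) + offset, -3, 3)
        diff = np.clip(np.array([-2, -1, 0, -2]) + offset, -3, 3)
        frames.append(make_records(same, diff, volunteer=f"v{i:03d}"))
    return pd.concat(frames, ignore_index=True)


class TestBootstrap:
    def test_no_sampling_variability_gives_zero_width(self, rng):
        records = _survey(6, rng, spread=False)
        res = bootstrap_statistic(
            records, lambda d: d["rating"].mean(), BootstrapConfig(n_boot=200, seed=0)
        )
        assert res.ci_low == res.ci_high == res.estimate

    def test_same_seed_is_bit_identical(self, rng):
        records = _survey(8, rng)
        cfg = BootstrapConfig(n_boot=300, seed=99)
        a = bootstrap_statistic(records, lambda d: d["rating"].mean(), cfg)
        b = bootstrap_statistic(records, lambda d: d["rating"].mean(), cfg)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert np.array_equal(a.replicates, b.replicates, equal_nan=True)

    def test_interval_contains_plug_in_estimate(self, rng):
        records = _survey(12, rng)
        res = bootstrap_statistic(
            records, lambda d: d["rating"].mean(), BootstrapConfig(n_boot=400, seed=3)
        )
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_mostly_undefined_statistic_raises_with_fraction(self, rng):
        records = _survey(5, rng)

        def brittle(df):
            # defined on the full sample, undefined whenever resampling
            # duplicates a volunteer (as nearly every replicate does)
            if df.groupby("volunteer_id").size().max() > 8:
                raise ValueError("degenerate resample")
            return float(df["rating"].mean())

        with pytest.raises(ValueError, match="undefined on"):
            bootstrap_statistic(records, brittle, BootstrapConfig(n_boot=50, seed=1))

    def test_needs_two_volunteers(self, rng):
        records = _survey(1, rng)
        with pytest.raises(ValueError, match="2 distinct volunteers"):
            bootstrap_statistic(records, lambda d: 0.0)


# ---------------------------------------------------------------------------
# rank tests


def brute_force_rank_p(a, b):
    """Exhaustive permutation two-sided p for the Mann-Whitney U (tie-aware)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = [
        ranks[list(c)].sum() - n1 * (n1 + 1) / 2.0
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    return float(np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us]))


class TestRankSum:
    def test_identical_lists_have_p_one(self):
        res = rank_sum_item_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_fully_separated_triples(self):
        res = rank_sum_item_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.10, abs=1e-12)  # 2/20 assignments

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.lists(st.integers(-3, 3), min_size=2, max_size=6),
        b=st.lists(st.integers(-3, 3), min_size=2, max_size=6),
    )
    def test_exact_path_matches_enumeration_oracle(self, a, b):
        res = rank_sum_item_test(a, b)
        assert res.p_value == pytest.approx(brute_force_rank_p(a, b), abs=1e-12)

    def test_large_sample_path_matches_scipy_asymptotics(self, rng):
        a = rng.integers(-3, 4, size=40)
        b = rng.integers(-2, 4, size=35)
        res = rank_sum_item_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_signed_rank_for_paired_inputs(self):
        x = [1, 2, 3, 2, 1, 0, 2, 3]
        y = [0, 1, 2, 2, 0, -1, 1, 2]
        res = signed_rank_test(x, y)
        ref = stats.wilcoxon(x, y)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestItemShift:
    def test_no_shift_anywhere(self):
        res = item_shift_summary([(0.5, 0.5), (1.0, 1.0), (-1.0, -1.0)])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.effect["mean_shift"] == 0.0

    def test_constant_nonzero_differences_flagged_degenerate(self):
        res = item_shift_summary([(1.0, 0.0)] * 4)
        assert res.degenerate and math.isinf(res.statistic) and res.p_value == 0.0
        assert res.effect["mean_shift"] == 1.0

    def test_matches_closed_form_t(self, rng):
        diffs = rng.normal(0.4, 0.4, size=12)
        pairs = [(d, 0.0) for d in diffs]
        res = item_shift_summary(pairs)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(12))
        assert res.statistic == pytest.approx(expected_t, abs=1e-12)
        assert res.df == (11.0,)
        ref = stats.ttest_1samp(diffs, 0.0)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


# ---------------------------------------------------------------------------
# chi-squared


def pearson_oracle(table):
    table = np.asarray(table, float)
    e = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float(((table - e) ** 2 / e).sum())


class TestChiSquared:
    def test_proportional_rows_give_zero(self):
        res = chi_squared_test([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.lists(st.integers(1, 30), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(lambda t: len({len(r) for r in t}) == 1)
    )
    def test_matches_pearson_formula_and_permutation_invariance(self, table):
        res = chi_squared_test(table)
        assert res.statistic == pytest.approx(pearson_oracle(table), rel=1e-12)
        arr = np.asarray(table)
        perm = chi_squared_test(arr[::-1, ::-1])
        assert perm.statistic == pytest.approx(res.statistic, rel=1e-12)
        scaled = chi_squared_test(arr * 3)
        assert scaled.statistic == pytest.approx(3 * res.statistic, rel=1e-12)

    def test_zero_margin_is_named(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_squared_test([[1, 0], [2, 0]])


# ---------------------------------------------------------------------------
# ANOVA


def oneway_ss_oracle(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(allv)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestOneWay:
    def test_identical_means_zero_f(self):
        res = oneway_anova([[1, 2, 3], [3, 2, 1], [2, 2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_ss_oracle_and_scipy(self, rng):
        groups = [rng.normal(m, 1, size=n) for m, n in ((0, 8), (0.5, 12), (1, 9))]
        res = oneway_anova(groups)
        assert res.statistic == pytest.approx(oneway_ss_oracle(groups), rel=1e-12)
        ref = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.7, 1, 14)
        res = oneway_anova([a, b])
        t = stats.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(float(t) ** 2, rel=1e-10)

    def test_all_constant_unequal_means_degenerate(self):
        res = oneway_anova([[1, 1, 1], [2, 2, 2]])
        assert res.degenerate and math.isinf(res.statistic)


def _long_table(rng, n_per_group=8, groups=("g1", "g2"), effect=0.5):
    rows = []
    sid = 0
    for g in groups:
        for _ in range(n_per_group):
            base = rng.normal(0, 1)
            rows.append((f"s{sid}", g, "A", base + rng.normal(0, 0.3)))
            rows.append((f"s{sid}", g, "B", base + effect + rng.normal(0, 0.3)))
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", "level", "y"])


def split_plot_ss_oracle(df):
    """Direct sums-of-squares decomposition for the balanced two-factor layout."""
    grand = df["y"].mean()
    w = df["level"].nunique()
    subj = df.groupby("subject")["y"].mean()
    sgrp = df.groupby("subject")["group"].first()
    gm = df.groupby("group")["y"].mean()
    lm = df.groupby("level")["y"].mean()
    cm = df.groupby(["group", "level"])["y"].mean()
    ng = sgrp.value_counts()
    n = len(subj)
    k = df["group"].nunique()
    ss_g = w * sum(ng[g] * (gm[g] - grand) ** 2 for g in gm.index)
    ss_s = w * sum((subj[s] - gm[sgrp[s]]) ** 2 for s in subj.index)
    ss_w = n * sum((lm[j] - grand) ** 2 for j in lm.index)
    ss_gw = sum(
        ng[g] * (cm[(g, j)] - gm[g] - lm[j] + grand) ** 2
        for g in gm.index for j in lm.index
    )
    ss_tot = ((df["y"] - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_s - ss_w - ss_gw
    f_between = (ss_g / (k - 1)) / (ss_s / (n - k))
    f_within = (ss_w / (w - 1)) / (ss_e / ((n - k) * (w - 1)))
    return f_between, f_within, ss_tot


class TestMixedAnova:
    def test_identical_within_levels_zero_f(self, rng):
        df = _long_table(rng, effect=0.0)
        df["y"] = df.groupby("subject")["y"].transform("mean")
        res = mixed_anova(df, dv="y", within="level", subject="subject",
                          between="group")
        assert res["within"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_ss_oracle(self, rng):
        df = _long_table(rng)
        res = mixed_anova(df, dv="y", within="level", subject="subject",
                          between="group")
        f_b, f_w, ss_tot = split_plot_ss_oracle(df)
        assert res["between"].statistic == pytest.approx(f_b, rel=1e-10)
        assert res["within"].statistic == pytest.approx(f_w, rel=1e-10)
        ss = res["_ss"]
        assert sum(v for k, v in ss.items() if k != "total") == pytest.approx(
            ss["total"], rel=1e-9
        )

    def test_matches_pingouin_on_balanced_design(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = _long_table(rng, n_per_group=10)
        res = mixed_anova(df, dv="y", within="level", subject="subject",
                          between="group")
        ref = pingouin.mixed_anova(data=df, dv="y", within="level",
                                   subject="subject", between="group")
        ref = ref.set_index("Source")
        assert res["between"].statistic == pytest.approx(
            float(ref.loc["group", "F"]), rel=1e-6
        )
        assert res["within"].statistic == pytest.approx(
            float(ref.loc["level", "F"]), rel=1e-6
        )
        assert res["interaction"].statistic == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-6
        )

    def test_repeated_measures_is_squared_paired_t(self, rng):
        df = _long_table(rng, groups=("only",))
        res = repeated_measures_anova(df, dv="y", within="level", subject="subject")
        wide = df.pivot(index="subject", columns="level", values="y")
        t = stats.ttest_rel(wide["A"], wide["B"]).statistic
        assert res.statistic == pytest.approx(float(t) ** 2, rel=1e-10)
        assert res.df == (1.0, float(len(wide) - 1))

    def test_missing_within_level_lists_subjects(self, rng):
        df = _long_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing a within level"):
            mixed_anova(df, dv="y", within="level", subject="subject",
                        between="group")
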