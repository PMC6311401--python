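"""Statistical battery: sample size, tests, agreement, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootaxis.stats import (
    SampleSizeParams,
    StatsError,
    bland_altman,
    bonferroni_adjust,
    dupont_plummer_n,
    kruskal_wallis,
    mann_whitney,
    paired_t,
    repeatability_report,
    shapiro_wilk,
    summaries_to_frame,
    summarize_aa,
)


# ---------------------------------------------------------------------------
# Dupont-Plummer paired sample size
# ---------------------------------------------------------------------------


class TestDupontPlummerN:
    def test_study_parameters_give_24(self):
        # SD of differences 5 degrees, minimum detectable difference 3
        # degrees, two-sided alpha 0.05, power 80%
        assert dupont_plummer_n(s=5, d=3, alpha=0.05, power=0.80) == 24

    def test_unit_effect_size(self):
        # normal-approximation bracket (1.96 + 0.8416)^2 ~ 7.85, then the
        # t correction pushes the fixed point to 10
        assert dupont_plummer_n(s=5, d=5, alpha=0.05, power=0.80) == 10

    def test_floor_of_two(self):
        assert dupont_plummer_n(s=5, d=500) == 2

    def test_monotone_in_s_and_d(self):
        grid = {}
        for s in range(2, 9):
            for d in range(1, 6):
                grid[(s, d)] = dupont_plummer_n(s=s, d=d)
        for s in range(2, 9):
            for d in range(1, 5):
                assert grid[(s, d)] >= grid[(s, d + 1)]  # non-increasing in d
        for d in range(1, 6):
            for s in range(2, 8):
                assert grid[(s, d)] <= grid[(s + 1, d)]  # non-decreasing in s

    def test_monotone_in_power(self):
        lo = dupont_plummer_n(s=5, d=3, power=0.70)
        hi = dupont_plummer_n(s=5, d=3, power=0.90)
        assert lo <= 24 <= hi

    def test_result_satisfies_the_relation(self):
        from scipy import stats as sps

        p = SampleSizeParams(s=5, d=3, alpha=0.05, power=0.80)
        n = dupont_plummer_n(p)
        k = n - 1
        need = (p.s / p.d) ** 2 * (
            sps.t.ppf(1 - p.alpha / 2, k) + sps.t.ppf(p.power, k)
        ) ** 2
        assert n >= need
        assert n - 1 < math.ceil(need)  # smallest such integer

    def test_invalid_params(self):
        with pytest.raises(StatsError):
            dupont_plummer_n(s=0, d=3)
        with pytest.raises(StatsError):
            dupont_plummer_n(s=5, d=3, alpha=1.5)


# ---------------------------------------------------------------------------
# Shapiro-Wilk
# ---------------------------------------------------------------------------


class TestShapiroWilk:
    def test_domain_errors(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])

    def test_type_one_error_rate_under_null(self):
        # 2000 normal samples of the study's size (n=31): the rejection
        # rate at alpha 0.05 must sit near its nominal level
        rng = np.random.default_rng(2024)
        rejections = sum(
            shapiro_wilk(rng.normal(size=31))[1] < 0.05 for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_detects_gross_non_normality(self):
        rng = np.random.default_rng(7)
        w, p = shapiro_wilk(rng.exponential(size=200) ** 2)
        assert p < 1e-6


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _mw_exact_oracle(a, b):
    """Exhaustive enumeration of all group labelings (tie-free data)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(x > y for x in a for y in b)
    mid = n1 * (len(b)) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        u = sum(x > y for x in pooled[mask] for y in pooled[~mask])
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_textbook_extremes(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)
        u, p = mann_whitney([1001, 1002, 1003, 1004, 1005], [1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 252)

    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 7 - (n1 > 4)))
            vals = rng.permutation(rng.normal(size=n1 + n2) * 10)
            a, b = vals[:n1], vals[n1:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(_mw_exact_oracle(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)

    def test_two_group_equivalence_with_normal_mw(self):
        # without ties, H for two groups equals the square of the
        # Mann-Whitney z statistic (chi-square with 1 df)
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=20), rng.normal(1.0, 1, size=15)
        h, _ = kruskal_wallis([a, b])
        u = sum(x > y for x in a for y in b)
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_null_pvalues_are_uniform(self):
        # permuting exchangeable data: p-values should be uniform
        rng = np.random.default_rng(21)
        base = rng.normal(size=24)
        ps = []
        for _ in range(2000):
            perm = rng.permutation(base)
            ps.append(kruskal_wallis([perm[:8], perm[8:16], perm[16:]])[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0]])


# ---------------------------------------------------------------------------
# Bonferroni / paired t / Bland-Altman
# ---------------------------------------------------------------------------


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01, 0.04]) == [0.02, 0.08]
        assert bonferroni_adjust([0.9, 0.9]) == [1.0, 1.0]
        assert bonferroni_adjust([0.3]) == [0.3]

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(3)
        ps = rng.uniform(size=8)
        adj = np.asarray(bonferroni_adjust(ps))
        assert np.all(adj >= ps)
        # order statistics preserved (capping at 1 may create ties)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= 0)

    def test_invalid_p(self):
        with pytest.raises(StatsError):
            bonferroni_adjust([0.5, 1.2])


class TestPairedT:
    def test_hand_computed(self):
        t, p, df = paired_t([1, 0, 2], [0, 0, 0])
        assert t == pytest.approx(np.sqrt(3))
        assert df == 2

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(StatsError):
            paired_t([1, 2, 3], [0, 1, 2])
        with pytest.raises(StatsError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            paired_t([1, 2], [1, 2, 3])


class TestBlandAltman:
    def test_hand_computed(self):
        res = bland_altman([1, -1, 2, 0, 3], [0, 0, 0, 0, 0])
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(np.sqrt(2.5))
        assert res.loa_upper == pytest.approx(1 + 1.96 * np.sqrt(2.5))

    def test_perfect_and_constant_offset_agreement(self):
        x = [3.0, 4.0, 5.0]
        res = bland_altman(x, x)
        assert (res.bias, res.loa_lower, res.loa_upper) == (0.0, 0.0, 0.0)
        res = bland_altman([v + 5 for v in x], x)
        assert res.bias == 5.0 and res.sd_diff == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_loa_invariants_hold_on_any_input(self, diffs, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(-10, 10, len(diffs))
        x = y + np.asarray(diffs)
        res = bland_altman(x, y)
        assert res.loa_lower == pytest.approx(res.bias - 1.96 * res.sd_diff)
        assert res.loa_upper == pytest.approx(res.bias + 1.96 * res.sd_diff)
        assert res.loa_lower <= res.bias <= res.loa_upper


# ---------------------------------------------------------------------------
# Study-level summaries
# ---------------------------------------------------------------------------


def _simulate_aa_table(rng, n_subjects=31, scale=10.0):
    teeth = (11, 12, 13, 21, 22, 23, 31, 32, 33, 41, 42, 43)
    rows = []
    meta = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        meta.append(
            {
                "subject": sid,
                "sex": "M" if rng.random() < 10 / 31 else "F",
                "age": float(rng.uniform(12, 40)),
                "angle_class": ["I", "II", "III"][rng.integers(3)],
            }
        )
        for t in teeth:
            rows.append(
                {"subject": sid, "tooth_fdi": t, "aa_deg": abs(rng.normal(0, scale))}
            )
    return pd.DataFrame(rows), pd.DataFrame(meta)


class TestSummarizeAA:
    def test_study_shape_summary(self):
        aa, meta = _simulate_aa_table(np.random.default_rng(0))
        summaries, report = summarize_aa(aa, meta)
        frame = summaries_to_frame(summaries)
        assert len(frame) == 12
        assert (frame["n"] == 31).all()
        s = frame.iloc[0]
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]
        assert set(report["test"]).issuperset({"shapiro_wilk", "sex_mann_whitney",
                                               "angle_class_kruskal_wallis"})

    def test_null_cohort_shows_no_group_differences(self):
        rng = np.random.default_rng(1)
        aa, meta = _simulate_aa_table(rng, scale=0.0)
        aa["aa_deg"] = rng.uniform(0, 0.5, len(aa))  # tiny estimator noise
        summaries, report = summarize_aa(aa, meta)
        assert summaries_to_frame(summaries)["median"].max() < 1.0
        comparisons = report[report["test"] != "shapiro_wilk"]
        assert (comparisons["p_adjusted"] > 0.05).all()

    def test_sex_type_one_rate_controlled_by_bonferroni(self):
        # identical AA distributions for both sexes: across simulated
        # cohorts the family-wise rejection rate must stay at or below 5%
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(200):
            aa, meta = _simulate_aa_table(rng)
            _, report = summarize_aa(aa, meta)
            sex = report[report["test"] == "sex_mann_whitney"]
            hits += int((sex["p_adjusted"] < 0.05).any())
        assert hits / 200 <= 0.05

    def test_missing_columns_named(self):
        aa, meta = _simulate_aa_table(np.random.default_rng(2), n_subjects=3)
        with pytest.raises(StatsError, match="angle_class"):
            summarize_aa(aa, meta.drop(columns=["angle_class"]))
        with pytest.raises(StatsError, match="aa_deg"):
            summarize_aa(aa.drop(columns=["aa_deg"]), meta)

    def test_pooled_sex_comparison_flag(self):
        aa, meta = _simulate_aa_table(np.random.default_rng(3), n_subjects=8)
        _, report = summarize_aa(aa, meta, pool_teeth_for_sex=True)
        assert "sex_mann_whitney_pooled" in set(report["test"])


class TestRepeatability:
    def test_identical_tables_agree_perfectly(self):
        aa, _ = _simulate_aa_table(np.random.default_rng(4), n_subjects=5)
        rep = repeatability_report(aa, aa.copy())
        assert (rep["bias"] == 0).all()
        assert (rep["loa_lower"] == 0).all() and (rep["loa_upper"] == 0).all()
        assert not rep["flagged"].any()

    def test_known_noise_model(self):
        # second measurement = first + N(0, 1 degree): bias ~ 0 and the
        # LoA half-width ~ 1.96 degrees, pooled over teeth at n=5
        rng = np.random.default_rng(5)
        first, _ = _simulate_aa_table(rng, n_subjects=5)
        second = first.copy()
        second["aa_deg"] = second["aa_deg"] + rng.normal(0, 1.0, len(second))
        rep = repeatability_report(first, second)
        pooled_bias = rep["bias"].mean()
        half_widths = (rep["loa_upper"] - rep["loa_lower"]) / 2
        assert abs(pooled_bias) < 0.5
        assert half_widths.mean() == pytest.approx(1.96, abs=0.5)

    def test_key_mismatch_rejected(self):
        aa, _ = _simulate_aa_table(np.random.default_rng(6), n_subjects=3)
        with pytest.raises(StatsError, match="keys"):
            repeatability_report(aa, aa[aa["subject"] != "S000"])
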