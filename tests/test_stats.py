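"""Agreement statistics and nonparametric tests against small-sample oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fractalct.stats import (
    bland_altman,
    bonferroni,
    inter_reader_agreement,
    rank_tests,
    variance_f_test,
)


def exact_mannwhitney_p(a, b, alternative="two-sided"):
    """Exhaustive-permutation Mann–Whitney p-value (no ties, n small)."""
    combined = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum((xi > yi) for xi in x for yi in y)

    observed = u_stat(a, b)
    us = [
        u_stat(combined[list(idx)], np.delete(combined, list(idx)))
        for idx in itertools.combinations(range(len(combined)), n1)
    ]
    us = np.array(us)
    if alternative == "less":
        return float((us <= observed).mean())
    if alternative == "greater":
        return float((us >= observed).mean())
    return float(min(1.0, 2 * min((us <= observed).mean(), (us >= observed).mean())))


def exact_wilcoxon_p(d, alternative="two-sided"):
    """Exhaustive sign-flip Wilcoxon signed-rank p-value (no ties/zeros)."""
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    totals = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((False, True), repeat=len(d))
    ]
    totals = np.array(totals)
    lo = (totals <= observed).mean()
    hi = (totals >= observed).mean()
    if alternative == "less":
        return float(lo)
    if alternative == "greater":
        return float(hi)
    return float(min(1.0, 2 * min(lo, hi)))


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = np.arange(3.0, 13.0)
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0
        assert ba.lower_limit == 0.0 and ba.upper_limit == 0.0
        assert ba.correlation.slope == pytest.approx(1.0)
        assert ba.correlation.r2 == 1.0

    def test_constant_bias_zero_width_limits(self):
        x = np.arange(3.0, 13.0)
        ba = bland_altman(x, x - 5.0)
        assert ba.mean_diff == pytest.approx(5.0)
        assert ba.upper_limit - ba.lower_limit == pytest.approx(0.0)

    def test_proportional_method_longhand(self):
        """reference 1..10 vs test = 0.8·reference, computed by hand:
        differences 0.2·ref have mean 0.2·5.5 = 1.1; test regressed on
        reference has slope exactly 0.8."""
        ref = np.arange(1.0, 11.0)
        ba = bland_altman(ref, 0.8 * ref)
        assert ba.mean_diff == pytest.approx(1.1)
        assert ba.correlation.slope == pytest.approx(0.8)
        assert ba.correlation.r2 == pytest.approx(1.0)

    @given(st.floats(-50, 50, allow_nan=False))
    def test_sign_convention_reference_minus_test(self, c):
        """Bland–Altman of (x, x+c) has mean difference −c, zero width."""
        x = np.array([3.0, 7.0, 11.0, 19.0])
        ba = bland_altman(x, x + c)
        assert ba.mean_diff == pytest.approx(-c, abs=1e-9)
        assert ba.upper_limit - ba.lower_limit == pytest.approx(0.0, abs=1e-9)

    def test_limits_bracket_mean(self, rng):
        ref = rng.normal(40, 10, 20)
        test = ref + rng.normal(2, 3, 20)
        ba = bland_altman(ref, test)
        assert ba.lower_limit <= ba.mean_diff <= ba.upper_limit

    def test_unit_rescaling_scales_linearly(self, rng):
        ref = rng.uniform(10, 50, 12)
        test = ref + rng.normal(0, 2, 12)
        ba1 = bland_altman(ref, test)
        ba10 = bland_altman(10 * ref, 10 * test)
        assert ba10.mean_diff == pytest.approx(10 * ba1.mean_diff)
        assert ba10.correlation.r2 == pytest.approx(ba1.correlation.r2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestRankTests:
    def test_disjoint_groups_exact_one_sided(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact one-sided p = 1/20."""
        reports = rank_tests({"a": [1, 2, 3], "b": [4, 5, 6]}, alternative="less")
        mw = reports[-1]
        assert mw.statistic == 0.0
        assert mw.p_raw == pytest.approx(1 / 20)
        assert "exact" in mw.method

    def test_identical_groups_p_one(self):
        reports = rank_tests({"a": [1.5, 2.5, 3.5], "b": [1.5, 2.5, 3.5]})
        assert reports[-1].p_raw == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(np.arange(1.0, 7.0))[:4]
        b = rng.uniform(0, 10, 5).round(3)
        reports = rank_tests({"a": a, "b": b})
        assert reports[-1].p_raw == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_paired_exact_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.uniform(0, 10, 7)
        y = x + rng.uniform(0.1, 3.0, 7) * rng.choice([-1, 1], 7)
        reports = rank_tests({"a": x, "b": y}, paired=True)
        assert reports[-1].p_raw == pytest.approx(exact_wilcoxon_p(x - y), abs=1e-12)

    def test_three_groups_include_omnibus_and_bonferroni(self):
        groups = {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5], "c": [10.0, 11, 12, 13]}
        reports = rank_tests(groups)
        assert reports[0].method == "kruskal-wallis"
        pairwise = reports[1:]
        assert len(pairwise) == 3
        for r in pairwise:
            assert r.n_comparisons == 3
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_tests({"a": [1, 2, 3], "b": [1, 2]}, paired=True)

    def test_all_tied_paired_differences_rejected(self):
        with pytest.raises(ValueError):
            rank_tests({"a": [1.0, 2.0], "b": [1.0, 2.0]}, paired=True)


class TestInterReader:
    def test_identical_readers(self):
        agg = inter_reader_agreement([10.0, 20, 30], [10.0, 20, 30])
        assert agg.median_discrepancy_pct == 0.0
        assert agg.iqr_pct == (0.0, 0.0)
        assert agg.spearman_rho == 1.0

    def test_doubled_reader_constant_discrepancy(self):
        agg = inter_reader_agreement([1.0, 2, 3], [2.0, 4, 6])
        assert np.allclose(agg.discrepancies_pct, 200.0 / 3)
        assert agg.spearman_rho == 1.0

    def test_three_pair_arithmetic_oracle(self):
        """(10,12),(20,19),(30,33): per-case discrepancies 2/11, 1/19.5,
        3/31.5 → 18.18 %, 5.13 %, 9.52 %; the median is 9.52 %."""
        agg = inter_reader_agreement([10.0, 20, 30], [12.0, 19, 33])
        assert agg.median_discrepancy_pct == pytest.approx(100 * 3 / 31.5, abs=1e-9)
        assert sorted(np.round(agg.discrepancies_pct, 1)) == [5.1, 9.5, 18.2]

    def test_scale_invariance(self, rng):
        r1 = rng.uniform(10, 50, 8)
        r2 = r1 * rng.uniform(0.8, 1.2, 8)
        a = inter_reader_agreement(r1, r2)
        b = inter_reader_agreement(10 * r1, 10 * r2)
        assert b.median_discrepancy_pct == pytest.approx(a.median_discrepancy_pct)
        assert b.spearman_rho == pytest.approx(a.spearman_rho)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            inter_reader_agreement([1.0, 2, 0.0], [1.0, 2, 3])


class TestVarianceFTest:
    def test_identical_lists(self):
        rep = variance_f_test([1.0, 2, 3], [1.0, 2, 3])
        assert rep.statistic == 1.0 and rep.p_raw == 1.0

    def test_threefold_scaling_gives_f_nine(self):
        a = [1.0, 2, 3, 4, 5]
        rep = variance_f_test(a, [3 * x for x in a])
        assert rep.statistic == pytest.approx(9.0)

    def test_f_distribution_oracle(self):
        """{1,2,3,4} vs {2,4,6,8}: F = 4 with df (3,3); the two-sided p
        equals 2·(1 − F_cdf(4; 3, 3)) = 0.2848 from the F distribution."""
        rep = variance_f_test([1.0, 2, 3, 4], [2.0, 4, 6, 8])
        assert rep.statistic == pytest.approx(4.0)
        assert rep.p_raw == pytest.approx(2 * sps.f.sf(4.0, 3, 3), abs=1e-12)
        assert rep.p_raw == pytest.approx(0.2848, abs=5e-4)

    def test_orientation_invariant(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 12)
        assert variance_f_test(a, b).statistic == variance_f_test(b, a).statistic

    def test_both_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 1.0], [2.0, 2.0])


class TestBonferroni:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6), st.integers(1, 10))
    def test_never_below_raw_never_above_one(self, ps, m):
        adj = bonferroni(ps, m)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_kruskal_wallis_null_calibration(self):
        """Type-I error of the omnibus test near its nominal 5 % level
        (500 null replicates of three N(0,1) groups of 10)."""
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            rejections += rank_tests(groups)[0].p_raw <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.025)
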