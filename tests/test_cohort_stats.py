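"""Normality gating, routed comparisons, correlations, exact tests.

The exact-test checks use independent brute-force oracles: Mann–Whitney
p-values by enumerating all label assignments, Fisher p-values by summing
the hypergeometric support directly.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as ss

from vrss.cohort_stats import (compare_groups, correlate, describe,
                               fisher_exact, normality_gate,
                               one_sample_vs_reference)
from vrss.errors import InvalidParameterError


# ---------------------------------------------------------------- oracles
def mw_exact_p_enumeration(x, y):
    """Two-sided Mann-Whitney p by enumerating all C(m+n, m) assignments."""
    pooled = list(x) + list(y)
    m = len(x)
    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)
    u_obs = u_stat(x, y)
    mn = m * len(y)
    # two-sided: double the smaller tail of min(U, mn-U)
    u_lo = min(u_obs, mn - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if min(u, mn - u) <= u_lo + 1e-9:
            count += 1
    return count / total


def fisher_two_sided_enumeration(table):
    """Sum hypergeometric probabilities of tables at most as likely."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------- gating
class TestNormalityGate:
    def test_normal_samples_pass_at_nominal_rate(self):
        hits = sum(normality_gate(np.random.default_rng(s).normal(size=1000))
                   == "normal" for s in range(100))
        assert hits >= 90  # 5 % nominal rejection, binomial tolerance

    def test_exponential_samples_detected_as_skewed(self):
        hits = sum(normality_gate(
            np.random.default_rng(s).exponential(size=1000)) == "skewed"
            for s in range(100))
        assert hits >= 99

    def test_constant_sample_is_skewed(self):
        assert normality_gate(np.full(100, 3.0)) == "skewed"

    def test_small_sample_forced_skewed(self):
        assert normality_gate([1.0, 2.0, 3.0]) == "skewed"


# ------------------------------------------------------------ comparisons
class TestCompareGroups:
    def test_identical_paired_samples_degenerate(self):
        x = np.arange(10, dtype=float)
        res = compare_groups(x, x.copy(), paired=True)
        assert res.degenerate and res.p_two_sided == 1.0

    def test_disjoint_samples_exact_mann_whitney(self):
        x = np.arange(1, 11, dtype=float)
        y = np.arange(11, 21, dtype=float)
        res = compare_groups(x, y, paired=False, route="skewed")
        assert res.test_name == "mann-whitney u"
        # U = 0 (or 100); exact two-sided p = 2 / C(20, 10)
        assert res.p_two_sided == pytest.approx(2 / 184756, rel=1e-9)

    def test_normal_route_uses_t_test(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(size=200), rng.normal(size=200))
        assert res.test_name == "independent t"

    def test_null_p_values_are_uniform(self):
        """Two same-distribution samples: p ~ U(0,1) across seeds."""
        ps = []
        for s in range(200):
            rng = np.random.default_rng(s)
            res = compare_groups(rng.normal(size=100), rng.normal(size=100))
            ps.append(res.p_two_sided)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_gated_pipeline_type_one_error(self):
        """Null rejection rate at alpha=.01 near nominal, n=28 split 10/18."""
        rej = 0
        reps = 2000
        for s in range(reps):
            rng = np.random.default_rng(s)
            res = compare_groups(rng.normal(size=10), rng.normal(size=18))
            rej += res.p_two_sided < 0.01
        assert 0.005 <= rej / reps <= 0.02

    def test_length_mismatch_in_paired_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_groups([], [1.0])

    def test_mann_whitney_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for m, n in [(3, 4), (5, 5), (6, 8)]:
            x = np.round(rng.normal(size=m), 2)
            y = np.round(rng.normal(0.5, 1, size=n), 2)
            if len(np.unique(np.concatenate([x, y]))) < m + n:
                continue  # oracle below assumes no ties
            res = compare_groups(x, y, paired=False)
            assert res.p_two_sided == pytest.approx(
                mw_exact_p_enumeration(x, y), abs=1e-12)


class TestOneSampleVsReference:
    def test_constant_at_reference_degenerate(self):
        res = one_sample_vs_reference(np.full(10, 10.0), ref=10.0)
        assert res.degenerate

    def test_small_shifted_sample_significant(self):
        res = one_sample_vs_reference(np.array([12.0, 13, 14, 15]), ref=10.0,
                                      route="normal")
        assert res.test_name == "one-sample t"
        assert res.p_two_sided < 0.05
        assert res.statistic > 0

    def test_level_near_nominal(self):
        rej = 0
        reps = 400
        for s in range(reps):
            rng = np.random.default_rng(s)
            res = one_sample_vs_reference(10.0 + rng.normal(size=500), ref=10.0)
            rej += res.p_two_sided < 0.01
        assert 0.002 <= rej / reps <= 0.025

    def test_tiny_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            one_sample_vs_reference([10.0])


# ------------------------------------------------------------ correlations
class TestCorrelate:
    def test_identity_gives_spearman_one(self):
        x = np.arange(10, dtype=float)
        res = correlate(x, x)
        assert res.method == "spearman" and res.r == pytest.approx(1.0)

    def test_balanced_symmetric_point_biserial_zero(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        res = correlate(x, y, x_dichotomous=True)
        assert res.method == "point_biserial"
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged_degenerate(self):
        res = correlate(np.ones(10), np.arange(10, dtype=float))
        assert res.degenerate and res.r is None

    def test_large_synthetic_cohort_recovers_copula_target(self):
        from vrss.synthetic import CohortConfig, generate_cohort
        tab = generate_cohort(CohortConfig(
            n_participants=2000, n_ss_positive=714, generate_rr=False,
            seed=11)).cohort_table()
        res = correlate(tab.ssq_total, tab.vlf_t6_10,
                        var_x="ssq_total", var_y="vlf_t6_10")
        assert res.r == pytest.approx(0.56, abs=0.10)

    @given(st.lists(st.integers(min_value=-1000, max_value=1000), min_size=6,
                    max_size=30, unique=True))
    def test_spearman_invariant_under_monotone_transform(self, values):
        x = np.asarray(values, dtype=float)
        y = np.linspace(0, 1, len(x)) + 0.3 * np.sin(np.arange(len(x)))
        r1 = correlate(x, y).r
        r2 = correlate(np.exp(x / 1000.0), y).r  # strictly monotone transform
        assert r1 == pytest.approx(r2, abs=1e-12)


# -------------------------------------------------------------- exact test
class TestFisherExact:
    def test_study_sex_table(self):
        assert fisher_exact([[3, 7], [5, 13]])["p_two_sided"] > 0.99

    def test_perfect_separation(self):
        res = fisher_exact([[10, 0], [0, 10]])
        assert res["p_two_sided"] == pytest.approx(2 / 184756, rel=1e-9)

    def test_zero_margin_degenerate(self):
        res = fisher_exact([[0, 0], [4, 6]])
        assert res["degenerate"] and res["p_two_sided"] == 1.0

    def test_matches_enumeration_for_all_small_tables(self):
        """Every 2x2 table with N <= 12 agrees with the hypergeometric sum."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        got = fisher_exact(table)["p_two_sided"]
                        want = fisher_two_sided_enumeration(table)
                        assert got == pytest.approx(want, abs=1e-12), table

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            fisher_exact([[1, -2], [3, 4]])


class TestDescribe:
    def test_skewed_route_median_iqr(self):
        out = describe([1, 2, 3, 4, 5], route="skewed")
        assert out["median"] == 3.0 and out["q1"] == 2.0 and out["q3"] == 4.0

    def test_constant_sample_sd_zero(self):
        out = describe(np.full(10, 7.0), route="normal")
        assert out["sd"] == 0.0

    def test_normal_route_mean_sd(self):
        out = describe(np.array([6.0, 8.0, 10.0, 8.0]), route="normal")
        assert out["mean"] == pytest.approx(8.0)
        assert "±" in out["display"]
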