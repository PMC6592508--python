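"""Factor splits, exact rank-sum testing and demographic comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sleeptrans.agreement import ErrorMatrix
from sleeptrans.stratify import (FACTOR_SPECS, compare_demographics,
                                 rank_sum_test, rank_test_errors,
                                 split_by_factor, stratification_report)


def brute_force_rank_sum_p(x, y):
    """Oracle: enumerate every assignment of pooled values to the x-slots,
    scoring each by the Mann-Whitney U statistic computed from pairwise
    comparisons (never from rank sums)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mean_u = nx * len(y) / 2.0
    dev = abs(u_stat(x, y) - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev - 1e-9:
            hits += 1
    return hits / total


def _factors(**cols):
    n = len(next(iter(cols.values())))
    base = {"subject_id": [f"S{i}" for i in range(n)]}
    base.update(cols)
    return pd.DataFrame(base)


class TestSplitByFactor:
    def test_psqi_boundary_joins_high_group(self):
        f = _factors(psqi=[3, 4, 5, 7])
        low, high, miss = split_by_factor(f, "psqi")
        assert low == {"S0", "S1"} and high == {"S2", "S3"} and miss == 0

    def test_se_boundary_joins_low_group(self):
        f = _factors(se=[85.0, 90.0, 95.0])
        low, high, _ = split_by_factor(f, "se")
        assert low == {"S0", "S1"} and high == {"S2"}

    def test_sex_nominal_split(self):
        f = _factors(sex=["female", "male", "male"])
        low, high, _ = split_by_factor(f, "sex")
        assert low == {"S0"} and high == {"S1", "S2"}

    def test_missing_values_counted(self):
        f = _factors(waso=[10.0, np.nan, 45.0])
        low, high, miss = split_by_factor(f, "waso")
        assert miss == 1 and low == {"S0"} and high == {"S2"}

    def test_unknown_factor_lists_valid_names(self):
        with pytest.raises(ValueError, match="psqi"):
            split_by_factor(_factors(psqi=[1]), "shoe_size")

    @given(values=st.lists(st.floats(0, 60, allow_nan=False), min_size=1, max_size=25))
    def test_partition_property(self, values):
        f = _factors(waso=values)
        low, high, miss = split_by_factor(f, "waso")
        assert low | high == set(f["subject_id"]) and not (low & high) and miss == 0


class TestRankSumTest:
    def test_separated_groups_exact_p(self):
        # {1,2,3} vs {10,11,12}: 2 of C(6,3)=20 assignments as extreme
        _, p = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = rank_sum_test([5, 7, 7], [7, 5, 7])
        assert p == 1.0

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for nx in range(1, 6):
            for ny in range(1, 11 - nx):
                if nx + ny > 10:
                    continue
                x = rng.integers(0, 4, nx).astype(float)  # heavy ties
                y = rng.integers(0, 4, ny).astype(float)
                _, p = rank_sum_test(x, y, method="exact")
                assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        _, p = rank_sum_test(x, y, method="normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_with_ties_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 6, 28).astype(float)
        _, p = rank_sum_test(x, y, method="normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(data=st.data())
    def test_invariant_under_monotone_transform(self, data):
        grid = st.integers(1, 500).map(lambda i: i / 10.0)  # coarse grid keeps
        x = data.draw(st.lists(grid, min_size=2, max_size=6))  # ties exact under
        y = data.draw(st.lists(grid, min_size=2, max_size=6))  # the transforms
        _, p = rank_sum_test(x, y)
        _, p_log = rank_sum_test(np.log(x), np.log(y))
        _, p_cube = rank_sum_test(np.power(x, 3), np.power(y, 3))
        assert p == pytest.approx(p_log, abs=1e-12)
        assert p == pytest.approx(p_cube, abs=1e-12)

    def test_power_against_doubled_location(self):
        # lognormal errors with doubled median should be detected often at n=23
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 100
        for _ in range(reps):
            low = rng.lognormal(math.log(50), 0.5, 11)
            high = rng.lognormal(math.log(100), 0.5, 12)
            _, p = rank_sum_test(low, high)
            rejections += p < 0.05
        assert rejections / reps > 0.5


class TestRankTestErrors:
    def test_reports_group_summaries(self):
        res = rank_test_errors([10.0, 20.0, 30.0], [100.0, 120.0],
                               factor="psqi", cutoff=5, cell=("D", "D"))
        assert res.testable
        assert res.group_low_mean == pytest.approx(20.0)
        assert res.group_high_mean == pytest.approx(110.0)
        assert res.n_low == 3 and res.n_high == 2

    def test_degenerate_groups_untestable(self):
        res = rank_test_errors([10.0], [20.0, 30.0])
        assert not res.testable and math.isnan(res.p_value)
        res = rank_test_errors([np.nan, np.nan], [20.0, 30.0])
        assert not res.testable

    def test_report_shape(self, small_cohort):
        from sleeptrans.pipeline import analyze_pairs

        result = analyze_pairs(small_cohort.pairs, factors=small_cohort.factors)
        report = result.stratification
        assert list(report.columns) == ["factor", "cutoff", "from", "to", "n_low",
                                        "n_high", "mean_low", "sd_low",
                                        "mean_high", "sd_high", "p"]
        assert len(report) == len(FACTOR_SPECS) * 16
        ok = report["p"].dropna()
        assert ((0 <= ok) & (ok <= 1)).all()


class TestCompareDemographics:
    def test_identical_groups_nonsignificant(self):
        f = _factors(sex=["female"] * 4 + ["male"] * 4,
                     waso=[10.0, 12.0, 14.0, 16.0] * 2)
        res = compare_demographics(f, "waso", by="sex")
        assert res.testable and res.p_value == pytest.approx(1.0)

    def test_separated_wake_time_detected(self):
        # means 9.7 vs 22.8 with moderate spread, n = 9 vs 14
        rng = np.random.default_rng(13)
        women = rng.normal(9.7, 6.0, 9)
        men = rng.normal(22.8, 8.0, 14)
        f = _factors(sex=["female"] * 9 + ["male"] * 14,
                     waso=np.concatenate([women, men]))
        res = compare_demographics(f, "waso", by="sex")
        assert res.p_value < 0.05
        assert res.mean_low < res.mean_high

    def test_age_split_grouping(self):
        f = _factors(age=[21, 22, 27, 28], tst=[300.0, 310.0, 390.0, 400.0])
        res = compare_demographics(f, "tst", by="age")
        assert res.n_low == 2 and res.n_high == 2

    def test_small_group_untestable(self):
        f = _factors(sex=["female", "male", "male"], waso=[10.0, 20.0, 30.0])
        res = compare_demographics(f, "waso", by="sex")
        assert not res.testable
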