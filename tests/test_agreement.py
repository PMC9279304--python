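import itertools

import numpy as np
import pytest
from scipy import stats

from airseg.agreement import (MeasurementTable, classify_reliability,
                              compare_methods, icc_two_way_mixed,
                              kruskal_wallis, mann_whitney_u)
from airseg.phantom import generate_measurement_table


def icc31_anova_oracle(values):
    """Straight sum-of-squares ICC(3,1) on an n x k matrix."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.mean()
    msr = k * ((values.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((values.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((values - grand) ** 2).sum()
    mse = (sst - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        t = MeasurementTable(["a", "b", "c"], ["m1", "m2"], vals)
        assert icc_two_way_mixed(t) == pytest.approx(1.0)

    def test_hand_table_matches_anova_oracle(self):
        vals = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0],
                         [7.0, 1.0], [10.0, 5.0]])
        t = MeasurementTable([f"s{i}" for i in range(5)], ["m1", "m2"], vals)
        assert icc_two_way_mixed(t) == pytest.approx(icc31_anova_oracle(vals),
                                                     abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        t = MeasurementTable([f"s{i}" for i in range(12)],
                             ["a", "b", "c"], vals)
        df = t.to_long()
        icc = pingouin.intraclass_corr(data=df, targets="subject",
                                       raters="method", ratings="value")
        ref = float(icc.loc[icc["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc_two_way_mixed(t) == pytest.approx(ref, abs=1e-10)

    def test_variance_components_recovery(self):
        t = generate_measurement_table(500, 2, noise_sd=1.0,
                                       between_subject_sd=3.0, seed=7)
        assert icc_two_way_mixed(t) == pytest.approx(0.9, abs=0.03)

    def test_invariant_to_per_method_shift(self, rng):
        vals = rng.normal(size=(10, 3))
        t1 = MeasurementTable([f"s{i}" for i in range(10)], list("abc"), vals)
        t2 = MeasurementTable([f"s{i}" for i in range(10)], list("abc"),
                              vals + np.array([5.0, -2.0, 11.0]))
        assert icc_two_way_mixed(t1) == pytest.approx(icc_two_way_mixed(t2),
                                                      abs=1e-10)

    def test_zero_variance_rejected(self):
        t = MeasurementTable(["a", "b"], ["m1", "m2"], np.ones((2, 2)))
        with pytest.raises(ZeroDivisionError):
            icc_two_way_mixed(t)


class TestReliability:
    @pytest.mark.parametrize("icc,label", [
        (0.92, "excellent"),
        (0.95, "excellent"),
        (0.80, "good"),
        (0.76, "good"),
        (0.90, "good"),       # boundary: strictly greater than 0.90
        (0.75, "below_good"),
        (0.50, "below_good"),
        (-0.2, "below_good"),
    ])
    def test_thresholds(self, icc, label):
        assert classify_reliability(icc) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(float("nan"))


def mwu_brute_force(x, y):
    """Oracle: U by all pairwise comparisons, exact p by enumerating every
    group assignment of the pooled sample."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)

    def u_of(a, b):
        u = 0.0
        for xa in a:
            for yb in b:
                u += (xa > yb) + 0.5 * (xa == yb)
        return u

    ux = u_of(x, y)
    u_obs = min(ux, n * m - ux)
    pooled = x + y
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n + m) if i not in idx]
        ua = u_of(a, b)
        if min(ua, n * m - ua) <= u_obs + 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


class TestMWU:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_multisets(self):
        u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9 / 2)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 7, 2)
            x = rng.integers(0, 8, n).astype(float)  # ties likely
            y = rng.integers(0, 8, m).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = mwu_brute_force(x, y)
            assert u == pytest.approx(u_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_u_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=15)
            u, p = mann_whitney_u(x, y)
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            u_scipy = min(res.statistic, len(x) * len(y) - res.statistic)
            assert u == pytest.approx(u_scipy, abs=1e-9)
            assert p == pytest.approx(res.pvalue, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def kw_rank_oracle(groups):
    """Direct midrank formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    big_n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r**2 / len(g)
        start += len(g)
    h = 12.0 / (big_n * (big_n + 1)) * h - 3 * (big_n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    h /= 1.0 - (counts**3 - counts).sum() / (big_n**3 - big_n)
    return h


class TestKW:
    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        # all midranks balanced; H small and p large
        assert h == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_all_constant_degenerate(self):
        h, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_table_matches_rank_oracle(self, rng):
        groups = [[6.5, 8.1, 9.0], [5.0, 6.5, 7.2, 7.9], [9.4, 10.1, 8.8]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_rank_oracle(groups), abs=1e-10)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=9), rng.normal(1, 1, 11), rng.normal(size=7)]
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_two_group_equivalence_with_mwu(self, rng):
        """For two tie-free groups, H = z^2, so the chi-square p equals the
        MWU normal-approximation p."""
        x = rng.normal(size=12)
        y = rng.normal(0.5, 1, 14)
        _, p_mwu = mann_whitney_u(x, y)
        _, p_kw = kruskal_wallis([x, y])
        assert p_kw == pytest.approx(p_mwu, abs=1e-6)


class TestNullCalibration:
    def test_kw_p_uniform_under_permuted_labels(self):
        """Under the null (identical group distributions) the KW p-value is
        approximately uniform."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(2000):
            pooled = rng.normal(size=24)
            groups = np.split(rng.permutation(pooled), 3)
            _, p = kruskal_wallis(groups)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestCompareMethods:
    def test_zero_noise_table_no_differences(self):
        t = generate_measurement_table(20, ["manual", "ai"], noise_sd=0.0,
                                       between_subject_sd=4.0, seed=2)
        report = compare_methods({"volume_cc": t})
        entry = report["volume_cc"]
        assert entry["icc"] == pytest.approx(1.0)
        assert entry["reliability"] == "excellent"
        assert not entry["pairwise"]["significant"].any()

    def test_location_shift_flagged(self):
        t = generate_measurement_table(
            40, ["manual", "ai"], per_method_bias=[0.0, 25.0],
            noise_sd=0.5, between_subject_sd=1.0, seed=3)
        report = compare_methods({"volume_cc": t})
        assert report["volume_cc"]["pairwise"]["significant"].all()

    def test_summary_matches_direct_recomputation(self):
        t = generate_measurement_table(15, 3, seed=4)
        report = compare_methods({"m": t})
        summary = report["m"]["summary"]
        np.testing.assert_allclose(summary["mean"], t.values.mean(axis=0))
        np.testing.assert_allclose(summary["sd"], t.values.std(axis=0, ddof=1))
        assert "kruskal_wallis" in report["m"]

    def test_long_format_round_trip(self):
        t = generate_measurement_table(6, 2, seed=5)
        back = MeasurementTable.from_long(t.to_long())
        np.testing.assert_allclose(back.values, t.values)
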