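"""Univariable estimators against hand formulas and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrcausal import (
    HarmonizedSet,
    SimulationConfig,
    egger,
    funnel_data,
    ivw,
    leave_one_out,
    simulate_two_sample,
    wald_ratio,
    weighted_median,
)
from tests.conftest import sim_harmonized


def hset(g, se_g, big, se_big):
    return HarmonizedSet.from_arrays(g, se_g, big, se_big)


class TestWaldRatio:
    def test_direct_ratio_and_first_order_se(self):
        est = wald_ratio(hset([0.2], [0.01], [0.1], [0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.05)

    def test_null_numerator_gives_or_one(self):
        est = wald_ratio(hset([0.2], [0.01], [0.0], [0.01]))
        assert est.beta == 0.0 and est.or_point == 1.0

    def test_joint_sign_flip_is_invariant(self):
        a = wald_ratio(hset([0.2], [0.01], [0.1], [0.01]))
        b = wald_ratio(hset([-0.2], [0.01], [-0.1], [0.01]))
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wald_ratio(hset([0.0], [0.01], [0.1], [0.01]))


class TestIvw:
    def test_perfect_proportionality_gives_zero_heterogeneity(self):
        est, het = ivw(hset([0.1, 0.2, 0.3], 0.01, [0.05, 0.10, 0.15], 0.01))
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0

    def test_hand_computed_q_and_i2(self):
        # two SNPs, w = 100 each: slope 0.5, Q = 100*(0.1^2+0.1^2) = 2
        est, het = ivw(hset([1.0, 1.0], 0.01, [0.4, 0.6], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert het.q == pytest.approx(2.0, abs=1e-10)
        assert het.df == 1
        assert het.i2 == pytest.approx(0.5, abs=1e-10)

    def test_single_snp_equals_wald_ratio(self):
        single = hset([0.2], [0.01], [0.1], [0.02])
        est, _ = ivw(single)
        ref = wald_ratio(single)
        assert est.beta == ref.beta and est.se == ref.se

    def test_fixed_and_random_effects_share_point_estimate(self):
        data = hset([0.1, 0.2, 0.3, 0.15], 0.01, [0.07, 0.09, 0.2, 0.05], [0.01, 0.02, 0.01, 0.03])
        fe, _ = ivw(data, "fixed")
        re, _ = ivw(data, "multiplicative_random")
        assert fe.beta == re.beta
        assert re.se >= fe.se

    def test_parameter_recovery_single_run(self):
        h, _ = sim_harmonized(SimulationConfig(n_snps=100, theta=0.3, seed=7))
        est, _ = ivw(h)
        assert abs(est.beta - 0.3) < 2 * est.se

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_q_invariant_to_common_rescaling(self, c):
        g = np.array([0.1, 0.25, 0.3, 0.18])
        big = np.array([0.06, 0.1, 0.2, 0.07])
        se = np.array([0.01, 0.02, 0.015, 0.03])
        _, het1 = ivw(hset(g, se, big, se))
        _, het2 = ivw(hset(c * g, c * se, c * big, c * se))
        assert het1.q == pytest.approx(het2.q, rel=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.1, 0.2, 0.3])
        est, pleio = egger(hset(g, 0.01, 0.02 + 0.5 * g, 0.01))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert pleio.intercept == pytest.approx(0.02, abs=1e-10)

    def test_orientation_makes_result_sign_invariant(self):
        g = np.array([0.1, -0.2, 0.3, -0.15])
        big = np.array([0.06, -0.13, 0.17, -0.08])
        a, pa = egger(hset(g, 0.01, big, 0.01))
        b, pb = egger(hset(-g, 0.01, -big, 0.01))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert pa.intercept == pytest.approx(pb.intercept, abs=1e-12)

    def test_minimum_snp_count_enforced(self):
        with pytest.raises(ValueError, match="3"):
            egger(hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.01))


class TestWeightedMedian:
    def test_symmetric_equal_weight_median(self):
        est = weighted_median(hset([1.0, 1.0, 1.0], 0.0001, [0.4, 0.5, 0.6], 0.01), 100, 0)
        assert est.beta == pytest.approx(0.5, abs=1e-10)

    def test_hand_interpolated_weighted_median(self):
        # ratios (1, 2, 10), normalized weights (0.5, 0.3, 0.2):
        # percentiles (0.25, 0.65, 0.90) -> 1 + (0.5-0.25)/(0.65-0.25) = 1.625
        g = np.array([1.0, 1.0, 1.0])
        big = np.array([1.0, 2.0, 10.0])
        se_big = 1.0 / np.sqrt(np.array([0.5, 0.3, 0.2]))
        est = weighted_median(hset(g, 0.0001, big, se_big), 100, 0)
        assert est.beta == pytest.approx(1.625, abs=1e-10)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.lists(st.floats(-2, 2), min_size=3, max_size=9))
    def test_equal_weights_reduce_to_interpolated_median(self, ratios):
        ratios = np.round(np.asarray(ratios), 6)
        g = np.ones_like(ratios)
        est = weighted_median(hset(g, 0.0001, ratios, 1.0), 100, 0)
        j = len(ratios)
        p = (np.arange(j) + 0.5) / j
        expected = float(np.interp(0.5, p, np.sort(ratios)))
        assert est.beta == pytest.approx(expected, abs=1e-9)

    def test_bootstrap_se_is_reproducible(self):
        data = hset([0.1, 0.2, 0.3, 0.25], 0.01, [0.06, 0.1, 0.14, 0.1], 0.01)
        a = weighted_median(data, 300, seed=42)
        b = weighted_median(data, 300, seed=42)
        assert a.se == b.se

    def test_breakdown_property_against_ivw(self):
        """With 60% valid SNPs and 40% strongly pleiotropic ones, the
        weighted median stays near theta while IVW is dragged away.

        The weighted median keeps a small finite-sample bias here (the 50%
        weight point sits at the upper edge of the valid SNPs' ratio
        cluster), so the check is on relative robustness, not exactness."""
        theta = 0.4
        wm_err, ivw_err = [], []
        for s in range(40):
            cfg = SimulationConfig(n_snps=30, theta=theta, invalid_fraction=0.4,
                                   pleiotropy_mean=0.08, pleiotropy_sd=0.005,
                                   n_exposure=1_030_836, n_outcome=79_055,
                                   target_r2=0.1866, binary_outcome=False,
                                   aligned_effects=True, seed=s)
            h, _ = sim_harmonized(cfg, select=False)
            wm_err.append(weighted_median(h, 200, seed=s).beta - theta)
            ivw_err.append(ivw(h)[0].beta - theta)
        assert abs(np.mean(ivw_err)) > 4 * abs(np.mean(wm_err))
        assert abs(np.mean(wm_err)) < 0.05
        assert abs(np.mean(ivw_err)) > 0.15


class TestLeaveOneOut:
    def test_no_influence_under_perfect_proportionality(self):
        res = leave_one_out(hset([0.1, 0.2, 0.3], 0.01, [0.05, 0.10, 0.15], 0.01))
        np.testing.assert_allclose(res.table.beta, 0.5, atol=1e-12)
        assert len(res.table) == 3
        assert res.table.max_influence.sum() == 1

    def test_planted_outlier_is_most_influential(self):
        cfg = SimulationConfig(n_snps=20, theta=0.5, seed=31)
        h, _ = sim_harmonized(cfg)
        t = h.table
        t.loc[t.index[4], "beta_outcome"] += 10 * t.loc[t.index[4], "se_outcome"]
        res = leave_one_out(h)
        flagged = res.table.loc[res.table.max_influence, "snp"].iloc[0]
        assert flagged == t.loc[t.index[4], "snp"]

    def test_row_count_matches_snp_count(self):
        h, _ = sim_harmonized(SimulationConfig(n_snps=17, theta=0.1, seed=3))
        assert len(leave_one_out(h).table) == h.n_snps


class TestFunnel:
    def test_single_snp_precision(self):
        table = funnel_data(hset([0.2], [0.01], [0.1], [0.05]))
        assert len(table) == 1
        assert table.precision.iloc[0] == pytest.approx(0.2 / 0.05)

    def test_empty_set_gives_empty_table(self):
        empty = HarmonizedSet.from_arrays([], [], [], [])
        assert funnel_data(empty).empty


def test_ivw_coverage_across_seeds():
    """95% CIs from random-effects IVW cover theta at close to nominal rate."""
    theta, n_seeds = 0.3, 1000
    covered = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_snps=93, n_exposure=1_030_836, n_outcome=79_055,
                               target_r2=0.1866, theta=theta, binary_outcome=False,
                               seed=s)
        h, _ = sim_harmonized(cfg, select=False)
        est, _ = ivw(h)
        if est.beta - 1.96 * est.se <= theta <= est.beta + 1.96 * est.se:
            covered += 1
    assert 0.93 <= covered / n_seeds <= 0.97
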