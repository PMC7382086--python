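"""Two-sample test machinery: the normal-approximation difference test, the
supremum test's grid arithmetic and scale, and the Brownian-motion tail
series."""

import math
import time

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_random_sample
from rmtl import (
    CompetingRisksSample,
    default_tau,
    diff_test,
    estimate_cif,
    sdiff_cumulative_difference,
    sdiff_sigma,
    sdiff_test,
    sup_bm_tail,
)


def two_groups(rng, n=80, censor_upper=20.0):
    return (
        make_random_sample(rng, n=n, censor_upper=censor_upper, group="1"),
        make_random_sample(rng, n=n, censor_upper=censor_upper, group="2"),
    )


class TestDiff:
    def test_identical_groups_give_null_result(self, toy_sample):
        res = diff_test(toy_sample, toy_sample, 3.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.delta == 0.0

    def test_group_swap_negates_z(self, rng):
        s1, s2 = two_groups(rng)
        tau = default_tau(s1, s2)
        a = diff_test(s1, s2, tau)
        b = diff_test(s2, s1, tau)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_p_is_two_sided_normal(self, rng):
        from scipy.stats import norm

        s1, s2 = two_groups(rng)
        res = diff_test(s1, s2, default_tau(s1, s2))
        assert res.p_value == pytest.approx(2 * norm.sf(abs(res.statistic)))

    def test_degenerate_variance_raises(self):
        a = CompetingRisksSample([5.0, 6.0, 1.0], [0, 0, 1], group="1")
        b = CompetingRisksSample([5.0, 6.0, 1.5], [0, 0, 1], group="2")
        # both groups event-free before tau=0.5 -> no information
        with pytest.raises(ValueError, match="degenerate|no events"):
            diff_test(a, b, 0.5)

    def test_null_p_values_approximately_uniform(self):
        """Under identical generating laws with no censoring the Diff
        p-values are near-uniform (Kolmogorov distance < 0.03)."""
        from rmtl import load_scenario, sample_pair

        config = load_scenario("A", n1=200, n2=200)
        pvals = []
        for child in np.random.SeedSequence(29).spawn(2000):
            rng = np.random.default_rng(child)
            s1, s2 = sample_pair(config, rng)
            pvals.append(diff_test(s1, s2, default_tau(s1, s2)).p_value)
        pvals = np.sort(pvals)
        ks = np.max(np.abs(pvals - np.arange(1, 2001) / 2000))
        assert ks < 0.03


class TestSupBMTail:
    def test_truncation_index_matches_bound(self):
        res = sup_bm_tail(1.0, 1e-10)
        assert res.m == 2  # ceil(sqrt(2)/pi * sqrt(log(1/(pi*1e-10))) - 1/2)

    def test_limits(self):
        assert sup_bm_tail(0.05).probability == pytest.approx(1.0, abs=1e-12)
        assert sup_bm_tail(10.0).probability < 1e-8

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sup_bm_tail(0.0)

    @given(st.floats(0.3, 5.0), st.floats(0.3, 5.0))
    def test_strictly_decreasing_in_x(self, x1, x2):
        lo, hi = sorted((x1, x2))
        if hi - lo > 1e-6:
            assert sup_bm_tail(lo).probability > sup_bm_tail(hi).probability

    def test_epsilon_only_perturbs_below_tolerance(self):
        for x in (0.8, 1.5, 2.5):
            a = sup_bm_tail(x, 1e-6).probability
            b = sup_bm_tail(x, 1e-12).probability
            assert abs(a - b) < 1e-6

    def test_fast(self):
        t0 = time.perf_counter()
        for x in np.linspace(0.2, 5.0, 200):
            sup_bm_tail(float(x))
        assert time.perf_counter() - t0 < 1.0


class TestSdiff:
    def test_identical_groups(self, toy_sample):
        res = sdiff_test(toy_sample, toy_sample, 3.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_group_swap_invariance(self, rng):
        s1, s2 = two_groups(rng)
        tau = default_tau(s1, s2)
        a = sdiff_test(s1, s2, tau)
        b = sdiff_test(s2, s1, tau)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_terminal_value_matches_diff_delta(self, rng):
        s1, s2 = two_groups(rng)
        tau = default_tau(s1, s2)
        _, path = sdiff_cumulative_difference(s1, s2, tau)
        d = diff_test(s1, s2, tau)
        assert path[-1] == pytest.approx(d.delta, abs=1e-12)

    def test_supremum_dominates_terminal_value(self, rng):
        for _ in range(5):
            s1, s2 = two_groups(rng)
            tau = default_tau(s1, s2)
            _, path = sdiff_cumulative_difference(s1, s2, tau)
            assert np.max(np.abs(path)) >= abs(path[-1]) - 1e-15

    def test_single_knot_cumulative_sum(self):
        # one cause-1 event per group at t=1; grid {1, tau}; the only
        # nonzero increment is (I2(1) - I1(1)) * (tau - 1)
        a = CompetingRisksSample([1.0, 9.9], [1, 0], group="1")
        b = CompetingRisksSample([1.0, 1.0, 9.9], [1, 1, 0], group="2")
        grid, path = sdiff_cumulative_difference(a, b, 6.0)
        d_at_1 = 2.0 / 3.0 - 0.5
        np.testing.assert_allclose(grid, [1.0, 6.0])
        np.testing.assert_allclose(path, [d_at_1 * 5.0, d_at_1 * 5.0],
                                   atol=1e-12)

    def test_sigma_closed_form_against_direct_sum(self, rng):
        """sigma^2 = (1-rho) sum s_i^2 + rho (sum s_i)^2 must equal the
        literal double sum over grid pairs."""
        s1, s2 = two_groups(rng, n=40)
        tau = default_tau(s1, s2).value
        c1, c2 = estimate_cif(s1, 1), estimate_cif(s2, 1)
        t = np.concatenate([s1.times[s1.causes > 0], s2.times[s2.causes > 0]])
        grid = np.unique(t[(t > 0) & (t <= tau)])
        if grid.size == 0 or grid[-1] < tau:
            grid = np.append(grid, tau)
        w = np.diff(np.append(grid, tau))
        v = np.asarray(c1.variance_at(grid)) + np.asarray(c2.variance_at(grid))
        for rho in (0.0, 0.5, 0.9):
            direct = 0.0
            for i in range(len(grid)):
                direct += w[i] ** 2 * v[i]
                for j in range(i + 1, len(grid)):
                    direct += (2 * rho * w[i] * w[j]
                               * math.sqrt(v[i] * v[j]))
            assert sdiff_sigma(s1, s2, tau, rho=rho) == pytest.approx(
                math.sqrt(direct), rel=1e-12
            )

    def test_sigma_zero_raises(self):
        a = CompetingRisksSample([5.0, 1.0], [0, 1], group="1")
        b = CompetingRisksSample([5.0, 1.2], [0, 1], group="2")
        with pytest.raises(ValueError, match="no events"):
            sdiff_sigma(a, b, 0.5)
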