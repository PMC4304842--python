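import numpy as np
import pytest
from scipy import stats

from crossurv._engine import PooledPermutation
from crossurv.survcore import SurvivalSample, build_risk_table
from crossurv.wlr_tests import (WeightSpec, _abs_sum_sf, _bvn_cdf, _bvn_rect,
                                shl_combined, weighted_logrank, wlr_covariance)

from conftest import exp_pair


class TestWeightedLogrank:
    def test_hand_example(self, toy_pair):
        t = build_risk_table(*toy_pair)
        res = weighted_logrank(t, WeightSpec.logrank())
        assert res.extras["U"] == pytest.approx(2 / 3)
        assert res.variance == pytest.approx(13 / 18)
        assert res.statistic == pytest.approx(0.7845, abs=1e-4)

    def test_mirrored_is_null(self, mirrored_pair):
        res = weighted_logrank(build_risk_table(*mirrored_pair))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_fh00_equals_logrank(self):
        for seed in range(4):
            s1, s2 = exp_pair(15, 12, seed=seed, censor_limit=7.0)
            t = build_risk_table(s1, s2)
            lr = weighted_logrank(t, WeightSpec.logrank())
            fh = weighted_logrank(t, WeightSpec.fleming_harrington(0, 0))
            assert fh.statistic == pytest.approx(lr.statistic)

    def test_group_exchange_negates_statistic(self):
        s1, s2 = exp_pair(15, 10, seed=5, censor_limit=6.0)
        t12 = build_risk_table(s1, s2)
        t21 = build_risk_table(s2, s1)
        for w in (WeightSpec.logrank(), WeightSpec.gehan(),
                  WeightSpec.tarone_ware(), WeightSpec.fleming_harrington(1, 1)):
            a = weighted_logrank(t12, w)
            b = weighted_logrank(t21, w)
            assert a.statistic == pytest.approx(-b.statistic)
            assert a.p_value == pytest.approx(b.p_value)

    def test_matches_lifelines_logrank(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test
        # rows past tau have a group at-risk count of zero, so their
        # observed-minus-expected and variance terms vanish: the truncated
        # statistic coincides with the untruncated one lifelines computes
        s1, s2 = exp_pair(30, 25, seed=7, censor_limit=8.0)
        t = build_risk_table(s1, s2)
        ours = weighted_logrank(t)
        ref = logrank_test(s1.times, s2.times, s1.status, s2.status)
        assert ours.statistic**2 == pytest.approx(ref.test_statistic, rel=1e-6)

    def test_degenerate_variance_flag(self):
        a = SurvivalSample([1.0], [1], 1)
        b = SurvivalSample([0.5], [0], 2)
        res = weighted_logrank(build_risk_table(a, b))
        assert res.degenerate and res.p_value == 1.0

    def test_normal_p_close_to_exhaustive_permutation_small_n(self):
        """Pooled n <= 8: the normal p stays within the permutation law's
        resolution of the exhaustive group-label permutation p."""
        from crossurv.simulate import Exponential, sample_survival_times
        worst = 0.0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            x1 = sample_survival_times(Exponential(0.25), 4, rng)
            x2 = sample_survival_times(Exponential(0.6), 4, rng)
            s1 = SurvivalSample(x1, np.ones(4, int), 1)
            s2 = SurvivalSample(x2, np.ones(4, int), 2)
            res = weighted_logrank(build_risk_table(s1, s2))
            pp = PooledPermutation(s1, s2)
            z = pp.logrank_z(pp.all_memberships())
            p_perm = np.mean(np.abs(z) >= abs(res.statistic) - 1e-12)
            worst = max(worst, abs(p_perm - res.p_value))
        assert worst < 0.15


class TestCovariance:
    def test_diagonal_matches_variance(self, toy_pair):
        t = build_risk_table(*toy_pair)
        w = WeightSpec.gehan()
        assert wlr_covariance(t, w, w) == pytest.approx(
            weighted_logrank(t, w).variance)

    def test_hand_lr_gw(self, toy_pair):
        t = build_risk_table(*toy_pair)
        cov = wlr_covariance(t, WeightSpec.logrank(), WeightSpec.gehan())
        assert cov == pytest.approx(13 / 6)

    def test_symmetry(self, null_pair):
        t = build_risk_table(*null_pair)
        wa, wb = WeightSpec.fleming_harrington(1, 0), WeightSpec.gehan()
        assert wlr_covariance(t, wa, wb) == pytest.approx(
            wlr_covariance(t, wb, wa))

    def test_fh_zero_weight_first_row(self, toy_pair):
        # FH with gamma>0 has weight 0 at the first event (S(t-)=1), so the
        # first row drops out of the covariance
        t = build_risk_table(*toy_pair)
        _, v = t.logrank_terms()
        w01 = WeightSpec.fleming_harrington(0, 1).evaluate(t)
        assert w01[0] == 0.0
        cov = wlr_covariance(t, WeightSpec.logrank(),
                             WeightSpec.fleming_harrington(0, 1))
        assert cov == pytest.approx(np.sum(w01[:3] * v[:3]))


class TestSHL:
    def test_mirrored_all_null(self, mirrored_pair):
        res = shl_combined(build_risk_table(*mirrored_pair))
        assert res.z1 == 0.0 and res.z2 == 0.0
        for r in (res.shl1, res.shl2, res.shl3):
            assert r.p_value == pytest.approx(1.0)

    def test_shl3_is_max_abs(self, null_pair):
        res = shl_combined(build_risk_table(*null_pair))
        assert res.shl3.statistic == pytest.approx(
            max(abs(res.z1), abs(res.z2)))
        assert abs(res.correlation) <= 1.0

    def test_perfect_correlation_limit(self):
        # at corr ~ 1 all three combined p-values collapse onto the
        # single-statistic two-sided p
        z = 1.7
        p_ref = 2 * stats.norm.sf(z)
        assert _abs_sum_sf(z, 1.0) == pytest.approx(p_ref)
        assert 1 - _bvn_rect(z, 1.0) == pytest.approx(p_ref)

    def test_bvn_cdf_against_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            rho = rng.uniform(-0.9, 0.9)
            h, k = rng.normal(size=2) * 1.5
            ref = stats.multivariate_normal(
                cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert _bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    def test_abs_sum_sf_against_monte_carlo(self):
        rng = np.random.default_rng(1)
        rho, s = 0.5, 1.2
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=200_000)
        mc = np.mean((np.abs(z[:, 0]) + np.abs(z[:, 1])) / 2 >= s)
        assert _abs_sum_sf(s, rho) == pytest.approx(mc, abs=0.005)
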