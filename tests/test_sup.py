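import numpy as np
import pytest
from scipy import optimize

from crossurv._engine import PooledPermutation
from crossurv.sup_tests import (bm_l2_eigenvalues, bridge_l2_eigenvalues,
                                brownian_sup_sf, cvm_tests,
                                hazard_difference_path, mks_test,
                                quadratic_form_sf, renyi_test)
from crossurv.survcore import SurvivalSample, build_risk_table
from crossurv.wlr_tests import weighted_logrank

from conftest import exp_pair


class TestReferenceLaws:
    def test_brownian_sup_five_percent_point(self):
        # the 5% point of sup|B| on [0,1] is 2.2414
        assert brownian_sup_sf(2.2414) == pytest.approx(0.05, abs=1e-4)
        assert brownian_sup_sf(0.0) == 1.0
        assert brownian_sup_sf(10.0) < 1e-8

    def test_cvm2_critical_value(self):
        # classical Cramer-von Mises omega^2 5% point
        lam = bridge_l2_eigenvalues(3000)
        crit = optimize.brentq(
            lambda x: quadratic_form_sf(x, lam) - 0.05, 0.1, 2.0)
        assert crit == pytest.approx(0.4614, abs=5e-4)

    def test_bm_l2_critical_value(self):
        lam = bm_l2_eigenvalues(3000)
        crit = optimize.brentq(
            lambda x: quadratic_form_sf(x, lam) - 0.05, 0.5, 5.0)
        assert crit == pytest.approx(1.6557, abs=5e-3)

    def test_eigenvalue_mass_equals_process_variance(self):
        assert bm_l2_eigenvalues(20_000).sum() == pytest.approx(0.5, abs=1e-4)
        assert bridge_l2_eigenvalues(20_000).sum() == pytest.approx(
            1 / 6, abs=1e-4)


class TestRenyi:
    def test_mirrored_null(self, mirrored_pair):
        res = renyi_test(build_risk_table(*mirrored_pair))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_supremum_dominates_endpoint(self):
        for seed in range(6):
            s1, s2 = exp_pair(20, 15, seed=seed, censor_limit=7.0)
            t = build_risk_table(s1, s2)
            ry = renyi_test(t)
            lr = weighted_logrank(t)
            assert ry.statistic >= abs(lr.statistic) - 1e-12

    def test_group_exchange_invariance(self):
        s1, s2 = exp_pair(15, 12, seed=3, censor_limit=6.0)
        a = renyi_test(build_risk_table(s1, s2))
        b = renyi_test(build_risk_table(s2, s1))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestMKS:
    def test_identical_groups(self, mirrored_pair):
        res = mks_test(build_risk_table(*mirrored_pair))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_group_exchange_invariance(self):
        s1, s2 = exp_pair(15, 12, seed=4, censor_limit=6.0)
        a = mks_test(build_risk_table(s1, s2))
        b = mks_test(build_risk_table(s2, s1))
        assert a.statistic == pytest.approx(b.statistic)

    def test_p_tracks_permutation_oracle(self):
        """Proportional-hazards draws at 20+20: the Brownian p-value stays
        near the permutation law of the same statistic (the asymptotic
        calibration is slightly conservative at this sample size)."""
        from crossurv.simulate import Exponential, sample_survival_times
        diffs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            x1 = sample_survival_times(Exponential(0.25), 20, rng)
            x2 = sample_survival_times(Exponential(0.5), 20, rng)
            s1 = SurvivalSample(x1, np.ones(20, int), 1)
            s2 = SurvivalSample(x2, np.ones(20, int), 2)
            res = mks_test(build_risk_table(s1, s2))
            pp = PooledPermutation(s1, s2)
            n1, d1 = pp.counts(pp.random_memberships(5000, rng))
            n2, d2 = pp.n - n1, pp.d - d1
            mask = (n1 >= 1) & (n2 >= 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                dl = np.cumsum(np.where(mask, d1 / np.maximum(n1, 1)
                                        - d2 / np.maximum(n2, 1), 0), axis=1)
                inc = np.where(mask, pp.d * (pp.n - pp.d)
                               / np.maximum(pp.n - 1, 1)
                               / np.maximum(n1 * n2, 1), 0)
            stat = (np.max(np.abs(np.where(mask, dl, 0)), axis=1)
                    / np.sqrt(inc.sum(axis=1)))
            p_perm = (1 + np.sum(stat >= res.statistic - 1e-12)) / 5001
            diffs.append(res.p_value - p_perm)
        assert max(abs(d) for d in diffs) < 0.12
        assert min(diffs) > -0.03  # never anti-conservative by much


class TestCVM:
    def test_identical_groups(self, mirrored_pair):
        c1, c2 = cvm_tests(build_risk_table(*mirrored_pair))
        assert c1.statistic == 0.0 and c1.p_value == 1.0
        assert c2.statistic == 0.0 and c2.p_value == 1.0

    def test_statistics_positive_and_exchange_invariant(self):
        s1, s2 = exp_pair(20, 20, seed=6, censor_limit=7.0)
        a1, a2 = cvm_tests(build_risk_table(s1, s2))
        b1, b2 = cvm_tests(build_risk_table(s2, s1))
        assert a1.statistic >= 0 and a2.statistic >= 0
        assert a1.statistic == pytest.approx(b1.statistic)
        assert a2.statistic == pytest.approx(b2.statistic)

    def test_sigma2_nondecreasing(self, null_pair):
        t = build_risk_table(*null_pair)
        _, _, s2 = hazard_difference_path(t)
        assert np.all(np.diff(s2) >= 0)

    def test_null_p_values_not_anticonservative(self):
        """Under exponential null pairs the empirical rejection rate at 5%
        stays at or below nominal plus Monte Carlo error (conservative is
        allowed for these statistics)."""
        rej1 = rej2 = 0
        n = 300
        for seed in range(n):
            s1, s2 = exp_pair(20, 20, seed=seed + 1000, censor_limit=10.0)
            c1, c2 = cvm_tests(build_risk_table(s1, s2))
            rej1 += c1.p_value <= 0.05
            rej2 += c2.p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert rej1 / n <= 0.05 + 3 * se
        assert rej2 / n <= 0.05 + 3 * se
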