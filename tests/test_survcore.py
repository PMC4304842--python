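import numpy as np
import pytest
from hypothesis import given, strategies as st

from crossurv.survcore import (NoEventsError, SurvivalSample, build_risk_table,
                               censoring_km, kaplan_meier, nelson_aalen,
                               pooled_sample)

from conftest import exp_pair


class TestSurvivalSample:
    def test_validation(self):
        with pytest.raises(ValueError):
            SurvivalSample([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            SurvivalSample([1.0], [2])
        with pytest.raises(ValueError):
            SurvivalSample([1.0, 2.0], [1])
        with pytest.raises(ValueError):
            SurvivalSample([], [])

    def test_counts(self):
        s = SurvivalSample([1.0, 2.0, 3.0], [1, 0, 1], group=2)
        assert s.size == 3 and s.n_events == 2 and s.group == 2


class TestRiskTable:
    def test_hand_example(self, toy_pair):
        t = build_risk_table(*toy_pair)
        np.testing.assert_array_equal(t.event_times, [1, 2, 3, 4])
        np.testing.assert_array_equal(t.n, [4, 3, 2, 1])
        np.testing.assert_array_equal(t.d1, [1, 0, 1, 0])
        # group 1 has nobody at risk at t=4, so tau is t=3
        assert t.tau_index == 2 and t.tau == 3.0

    def test_identical_samples_split_evenly(self, mirrored_pair):
        t = build_risk_table(*mirrored_pair)
        np.testing.assert_allclose(t.d1, t.d / 2)
        np.testing.assert_allclose(t.n1, t.n / 2)

    def test_no_events_raises(self):
        a = SurvivalSample([1.0, 2.0], [0, 0], 1)
        b = SurvivalSample([1.5], [0], 2)
        with pytest.raises(NoEventsError):
            build_risk_table(a, b)

    def test_censored_at_event_time_still_at_risk(self):
        # tie convention: events precede censorings
        a = SurvivalSample([2.0, 2.0], [1, 0], 1)
        b = SurvivalSample([2.0, 3.0], [1, 1], 2)
        t = build_risk_table(a, b)
        assert t.n[0] == 4  # the subject censored at 2 counts at risk at 2

    def test_d1_sum_bounded_by_group1_events(self):
        for seed in range(5):
            s1, s2 = exp_pair(12, 9, seed=seed, censor_limit=6.0)
            t = build_risk_table(s1, s2)
            assert t.d1.sum() <= s1.n_events
            # equality when no group-1 event falls after tau
            if (s1.times[s1.status == 1] <= t.tau).all():
                assert t.d1.sum() == s1.n_events

    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariants_hold_on_random_data(self, seed):
        s1, s2 = exp_pair(8, 6, seed=seed, censor_limit=5.0)
        try:
            t = build_risk_table(s1, s2)
        except NoEventsError:
            return
        assert np.all(np.diff(t.event_times) > 0)
        assert np.all(np.diff(t.n) <= 0)
        assert np.all((1 <= t.d) & (t.d <= t.n))
        assert np.all((0 <= t.d1) & (t.d1 <= np.minimum(t.d, t.n1)))
        np.testing.assert_array_equal(t.n, t.n1 + t.n2)
        m = t.tau_index + 1
        assert np.all(t.n1[:m] >= 1) and np.all(t.n2[:m] >= 1)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        s = SurvivalSample([1.0, 2.0], [1, 1])
        km = kaplan_meier(s)
        np.testing.assert_allclose(km.values, [0.5, 0.0])
        assert km.at(0.5) == 1.0 and km.at(1.5) == 0.5

    def test_censoring_freezes_curve(self):
        s = SurvivalSample([1.0, 2.0], [1, 0])
        km = kaplan_meier(s)
        np.testing.assert_allclose(km.at([1.0, 5.0]), [0.5, 0.5])

    def test_all_censored_flat_one(self):
        s = SurvivalSample([1.0, 2.0], [0, 0])
        km = kaplan_meier(s)
        assert km.at(10.0) == 1.0

    def test_left_limits(self):
        s = SurvivalSample([1.0, 2.0], [1, 1])
        km = kaplan_meier(s)
        assert km.left_limit(1.0) == 1.0
        assert km.left_limit(2.0) == 0.5
        assert km.left_limit(1.5) == 0.5

    def test_pooled_km_equals_risk_table_product(self, null_pair):
        t = build_risk_table(*null_pair)
        km = kaplan_meier(pooled_sample(*null_pair))
        prod = np.cumprod(1.0 - t.d / t.n)
        np.testing.assert_allclose(km.at(t.event_times), prod)

    def test_no_censoring_matches_ecdf(self):
        s1, _ = exp_pair(25, 5, seed=3)
        km = kaplan_meier(s1)
        ecdf_surv = 1.0 - np.searchsorted(np.sort(s1.times), km.knots,
                                          side="right") / s1.size
        np.testing.assert_allclose(km.values, ecdf_surv, atol=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        s1, _ = exp_pair(40, 5, seed=9, censor_limit=8.0)
        km = kaplan_meier(s1)
        kmf = lifelines.KaplanMeierFitter().fit(s1.times, s1.status)
        ref = kmf.survival_function_at_times(km.knots).to_numpy()
        np.testing.assert_allclose(km.values, ref, atol=1e-10)


class TestNelsonAalen:
    def test_two_events(self):
        s = SurvivalSample([1.0, 2.0], [1, 1])
        na = nelson_aalen(s)
        np.testing.assert_allclose(na.values, [0.5, 1.5])
        assert na.at(0.5) == 0.0

    def test_single_subject(self):
        na = nelson_aalen(SurvivalSample([1.0], [1]))
        assert na.at(1.0) == 1.0 and na.variance_at(1.0) == 1.0

    def test_all_censored_flat_zero(self):
        na = nelson_aalen(SurvivalSample([1.0, 2.0], [0, 0]))
        assert na.at(10.0) == 0.0


class TestCensoringKM:
    def test_no_censoring_flat_one(self):
        c = censoring_km(SurvivalSample([1.0, 2.0], [1, 1]))
        assert c.at(10.0) == 1.0

    def test_event_then_censor(self):
        c = censoring_km(SurvivalSample([1.0, 2.0], [0, 1]))
        assert c.at(1.0) == 0.5

    def test_mirror_of_km(self):
        c = censoring_km(SurvivalSample([1.0, 2.0], [0, 0]))
        np.testing.assert_allclose(c.values, [0.5, 0.0])
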