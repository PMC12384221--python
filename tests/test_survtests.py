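import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy.stats import multivariate_normal, norm

import survdesign as sd
from survdesign.survtests import (
    MAXCOMBO_2,
    MAXCOMBO_3,
    FHWeight,
    _mvn_equicoordinate_cdf,
    risk_sets_from_arrays,
    rmst_test_arrays,
    surv_prob_test_arrays,
)

from conftest import dataset_from_arrays, fixed_design


def _random_two_arm(rng, n):
    time = np.round(rng.exponential(3.0, n), 2) + 0.01  # ties on purpose
    event = rng.random(n) < 0.75
    arm = (rng.random(n) < 0.5).astype(np.int8)
    if event[arm == 0].sum() == 0 or event[arm == 1].sum() == 0:
        event[:2] = True
        arm[0], arm[1] = 0, 1
    return time, event, arm


class TestRiskSets:
    def test_hand_enumeration_no_censoring(self):
        # arm0 events {1,2}, arm1 events {3,4}: pooled risk sets 4,3,2,1
        ds = dataset_from_arrays([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        t = sd.build_risk_sets(ds)
        np.testing.assert_array_equal(t.time, [1, 2, 3, 4])
        np.testing.assert_array_equal(t.y, [4, 3, 2, 1])
        np.testing.assert_array_equal(t.d0, [1, 1, 0, 0])
        np.testing.assert_array_equal(t.d1, [0, 0, 1, 1])

    def test_all_censored_gives_empty_table(self):
        ds = dataset_from_arrays([1, 2, 3], [0, 0, 0], [0, 1, 0])
        assert sd.build_risk_sets(ds).n_rows == 0

    def test_single_event_full_risk_set(self):
        time = np.arange(1.0, 11.0)
        event = np.zeros(10, bool)
        event[0] = True
        t = sd.build_risk_sets(dataset_from_arrays(time, event, [0, 1] * 5))
        assert t.n_rows == 1
        assert t.y[0] == 10 and t.d[0] == 1

    def test_censored_tied_with_event_stays_at_risk(self):
        ds = dataset_from_arrays([2, 2, 3], [1, 0, 1], [0, 1, 1])
        t = sd.build_risk_sets(ds)
        assert t.y[0] == 3  # censored-at-2 counted at risk at time 2


class TestWeightedLogrank:
    def test_mirror_data_symmetric(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        arm = np.array([0, 0, 0, 1, 1, 1])
        res = sd.weighted_logrank(
            sd.build_risk_sets(dataset_from_arrays(time, event, arm)))
        assert res.statistic == pytest.approx(0.0, abs=1e-14)
        assert res.p == pytest.approx(0.5)
        assert not res.reject

    def test_hand_enumerated_four_event_fixture(self):
        # control events {1,3}, treatment events {2,4}, no censoring:
        #  t=1: Y=4,Y0=2,d0=1 -> O-E = 1 - 2/4        = 1/2;  V = 12/48
        #  t=2: Y=3,Y0=1,d0=0 -> O-E = 0 - 1/3        = -1/3; V = 4/18
        #  t=3: Y=2,Y0=1,d0=1 -> O-E = 1 - 1/2        = 1/2;  V = 1/4
        #  t=4: Y=1            -> O-E = 0;             V = 0
        ds = dataset_from_arrays([1, 3, 2, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        res = sd.weighted_logrank(sd.build_risk_sets(ds))
        u_hand = 0.5 - 1.0 / 3.0 + 0.5
        v_hand = 0.25 + 2.0 / 9.0 + 0.25
        assert res.statistic == pytest.approx(u_hand, rel=1e-12)
        assert res.z == pytest.approx(u_hand / np.sqrt(v_hand), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n", [8, 20])
    def test_fh00_matches_lifelines_chisq(self, seed, n):
        """FH(0,0) z^2 equals the classical log-rank chi-square."""
        time, event, arm = _random_two_arm(np.random.default_rng(seed), n)
        res = sd.weighted_logrank(risk_sets_from_arrays(time, event, arm))
        oracle = logrank_test(time[arm == 0], time[arm == 1],
                              event[arm == 0], event[arm == 1])
        assert res.z ** 2 == pytest.approx(oracle.test_statistic, abs=1e-10)

    def test_fh_weighted_matches_lifelines(self):
        time, event, arm = _random_two_arm(np.random.default_rng(9), 30)
        res = sd.weighted_logrank(risk_sets_from_arrays(time, event, arm),
                                  FHWeight(0, 1))
        oracle = logrank_test(time[arm == 0], time[arm == 1],
                              event[arm == 0], event[arm == 1],
                              weightings="fleming-harrington", p=0, q=1)
        assert res.z ** 2 == pytest.approx(oracle.test_statistic, abs=1e-8)

    def test_no_events_p_one(self):
        ds = dataset_from_arrays([1, 2], [0, 0], [0, 1])
        res = sd.weighted_logrank(sd.build_risk_sets(ds))
        assert res.p == 1.0 and not res.reject


class TestMaxCombo:
    def test_single_component_reduces_to_logrank(self):
        time, event, arm = _random_two_arm(np.random.default_rng(5), 24)
        table = risk_sets_from_arrays(time, event, arm)
        mc = sd.maxcombo(table, [FHWeight(0, 0)])
        lr = sd.weighted_logrank(table)
        assert mc.p == pytest.approx(lr.p, rel=1e-12)

    def test_duplicate_weights_collapse(self):
        time, event, arm = _random_two_arm(np.random.default_rng(6), 24)
        table = risk_sets_from_arrays(time, event, arm)
        mc = sd.maxcombo(table, [FHWeight(0, 0), FHWeight(0, 0)])
        lr = sd.weighted_logrank(table)
        assert mc.p == pytest.approx(lr.p, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_bonferroni_sandwich(self, seed):
        """min component p <= maxcombo p <= K * min component p."""
        time, event, arm = _random_two_arm(np.random.default_rng(seed), 40)
        table = risk_sets_from_arrays(time, event, arm)
        mc = sd.maxcombo(table, MAXCOMBO_3)
        comp_p = [sd.weighted_logrank(table, w).p for w in MAXCOMBO_3]
        assert mc.p >= min(comp_p) - 1e-9
        assert mc.p <= 3 * min(comp_p) + 1e-9

    def test_positive_z_means_treatment_better(self):
        # all control events early, treatment event-free
        time = np.array([0.5, 0.7, 0.9, 5.0, 5.0, 5.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        arm = np.array([0, 0, 0, 1, 1, 1])
        table = risk_sets_from_arrays(time, event, arm)
        assert sd.weighted_logrank(table).z > 0
        assert sd.maxcombo(table, MAXCOMBO_2).z > 0

    def test_equicoordinate_cdf_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            z = rng.uniform(-1.0, 3.5)
            a = rng.uniform(0.5, 0.98, 3)
            corr = np.array([[1, a[0], a[1]], [a[0], 1, a[2]],
                             [a[1], a[2], 1]])
            if np.linalg.eigvalsh(corr).min() < 1e-4:
                continue
            for k in (2, 3):
                oracle = multivariate_normal.cdf(
                    np.full(k, z), mean=np.zeros(k), cov=corr[:k, :k],
                    maxpts=2_000_000, abseps=1e-9, releps=0,
                    rng=np.random.default_rng(0))
                assert _mvn_equicoordinate_cdf(z, corr[:k, :k]) == \
                    pytest.approx(oracle, abs=2e-5)


class TestKaplanMeierGreenwood:
    def test_binomial_identity_without_censoring(self):
        # 10 subjects, 4 events by t: S = 0.6, var = 0.6*0.4/10
        time = np.array([1, 2, 3, 4, 9, 9, 9, 9, 9, 9], dtype=float)
        event = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        est = sd.km_with_greenwood(time, event, 5.0)
        assert est.surv == pytest.approx(0.6, rel=1e-12)
        assert est.var == pytest.approx(0.6 * 0.4 / 10, rel=1e-12)

    def test_before_first_event(self):
        est = sd.km_with_greenwood(np.array([2.0, 3.0]), np.array([1, 1]), 1.0)
        assert est.surv == 1.0 and est.var == 0.0

    def test_hand_product_with_censoring(self):
        # pattern {1+, 2, 3+, 4}: S(3.5) = 2/3, Greenwood = (2/3)^2 / 6
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([0, 1, 0, 1])
        est = sd.km_with_greenwood(time, event, 3.5)
        assert est.surv == pytest.approx(2 / 3, rel=1e-12)
        assert est.var == pytest.approx((2 / 3) ** 2 / 6, rel=1e-12)
        # ... and S(4) = 2/3 * (1 - 1/1) = 0
        assert sd.km_with_greenwood(time, event, 4.0).surv == 0.0

    def test_beyond_last_observation_flagged(self):
        est = sd.km_with_greenwood(np.array([1.0, 2.0]), np.array([1, 0]), 3.0)
        assert not est.estimable

    def test_matches_lifelines(self):
        time, event, arm = _random_two_arm(np.random.default_rng(11), 40)
        t0 = float(np.median(time))
        est = sd.km_with_greenwood(time, event, t0)
        kmf = KaplanMeierFitter().fit(time, event)
        assert est.surv == pytest.approx(
            float(kmf.survival_function_at_times(t0).iloc[0]), rel=1e-10)


class TestSurvProbTest:
    def test_identical_arms_z_zero(self):
        time = np.array([1.0, 2.0, 3.5, 1.0, 2.0, 3.5])
        event = np.array([1, 1, 0, 1, 1, 0])
        arm = np.array([0, 0, 0, 1, 1, 1])
        res = surv_prob_test_arrays(time, event, arm, 3.0)
        assert res.z == pytest.approx(0.0, abs=1e-14)

    def test_inestimable_arm_p_one(self):
        time = np.array([1.0, 1.5, 5.0, 5.0])
        event = np.array([1, 0, 0, 0])
        arm = np.array([0, 0, 1, 1])
        res = surv_prob_test_arrays(time, event, arm, 3.0)
        assert res.p == 1.0 and res.note


class TestRMST:
    def test_toy_step_areas(self):
        # {1, 2+, 3}: mu(3) = 1*1 + (2/3)*2 = 7/3; var = (1/6)(4/3)^2
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])
        est = sd.rmst_estimate(time, event, 3.0)
        assert est.rmst == pytest.approx(7 / 3, rel=1e-12)
        assert est.var == pytest.approx((1 / 6) * (4 / 3) ** 2, rel=1e-12)

    def test_no_events_gives_tau(self):
        est = sd.rmst_estimate(np.array([5.0, 6.0]), np.array([0, 0]), 4.0)
        assert est.rmst == 4.0 and est.var == 0.0

    def test_exact_step_integration_oracle(self):
        """Area under the KM curve re-derived point by point."""
        rng = np.random.default_rng(13)
        time, event, _ = _random_two_arm(rng, 50)
        tau = 4.0
        est = sd.rmst_estimate(time, event, tau)
        kmf = KaplanMeierFitter().fit(time, event)
        grid = np.concatenate(([0.0], np.sort(time[time < tau]), [tau]))
        vals = kmf.survival_function_at_times(grid[:-1]).to_numpy()
        oracle = float((vals * np.diff(grid)).sum())
        assert est.rmst == pytest.approx(oracle, abs=1e-12)

    def test_matches_lifelines_rmst(self):
        time, event, _ = _random_two_arm(np.random.default_rng(14), 60)
        kmf = KaplanMeierFitter().fit(time, event)
        oracle = restricted_mean_survival_time(kmf, t=3.5)
        assert sd.rmst_estimate(time, event, 3.5).rmst == \
            pytest.approx(float(oracle), rel=1e-9)

    def test_uncensored_exponential_converges_to_closed_form(self):
        lam = np.log(2) / 3
        model = sd.PiecewiseExpModel.exponential(lam)
        x = model.sample(200_000, np.random.default_rng(15))
        est = sd.rmst_estimate(x, np.ones_like(x, bool), 4.5)
        closed = model.rmst(4.5)
        assert est.rmst == pytest.approx(closed, abs=3 * np.sqrt(est.var))
        assert abs(est.rmst - closed) < 0.02

    def test_mirror_identical_arms_z_zero(self):
        time = np.array([1.0, 2.0, 4.5, 1.0, 2.0, 4.5])
        event = np.array([1, 1, 0, 1, 1, 0])
        arm = np.array([0, 0, 0, 1, 1, 1])
        res = rmst_test_arrays(time, event, arm, 4.5)
        assert res.z == 0.0

    def test_inestimable_flagged(self):
        time = np.array([1.0, 2.0])
        event = np.array([1, 0])
        est = sd.rmst_estimate(time, event, 4.5)
        assert not est.estimable


class TestFHWeightBasics:
    def test_zero_zero_weight_is_one(self):
        s = np.array([1.0, 0.8, 0.3])
        np.testing.assert_array_equal(FHWeight(0, 0).weights(s), 1.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            FHWeight(-0.5, 0)
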