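"""Survival estimators and IPCW model-comparison metrics.

Small instances are checked against hand computations or brute-force pair
enumeration; lifelines and scikit-survival serve as independent oracles on
random data.
"""

import numpy as np
import pandas as pd
import pytest

from habistrat import survival as sv
from habistrat.cohort import simulate_survival_endpoints


class TestKaplanMeier:
    def test_hand_product_on_three_events(self):
        # times (2,4,6) all events: S(5) = (2/3)(1/2) = 1/3
        curve = sv.kaplan_meier([2, 4, 6], [1, 1, 1])
        assert curve.evaluate(5.0) == pytest.approx(1 / 3)
        assert curve.evaluate(1.0) == 1.0

    def test_all_censored_gives_unit_survival(self):
        curve = sv.kaplan_meier([3, 5, 7], [0, 0, 0])
        for t in (1.0, 6.0, 100.0):
            assert curve.evaluate(t) == 1.0

    def test_last_value_carried_beyond_follow_up(self):
        curve = sv.kaplan_meier([2, 4, 9], [1, 1, 0])
        assert curve.evaluate(100.0) == pytest.approx(curve.evaluate(4.0))

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        e[0] = 1
        curve = sv.kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = curve.evaluate(curve.times)
        theirs = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(5, size=50)
        curve = sv.kaplan_meier(t, np.ones(50, dtype=int))
        for q in (0.2, 0.5, 0.9):
            x = np.quantile(t, q)
            assert curve.evaluate(x) == pytest.approx(np.mean(t > x))


class TestLogrank:
    def test_exchangeable_groups_give_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, dof, p = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert (dof, p) == (1, pytest.approx(1.0))

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import multivariate_logrank_test
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        e[:3] = 1
        g = rng.integers(0, 2, size=60)
        chi2, dof, p = sv.logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_three_groups_dof(self, rng):
        t = rng.exponential(10, size=90)
        e = np.ones(90, dtype=int)
        g = np.repeat([0, 1, 2], 30)
        _, dof, _ = sv.logrank_test(t, e, g)
        assert dof == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_rescaling_covariate_rescales_coefficient(self, rng):
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"t": t, "e": 1, "x": x, "x10": 10 * x})
        fit1 = sv.cox_model(df, "t", "e", ["x"])
        fit2 = sv.cox_model(df, "t", "e", ["x10"])
        assert fit2["coef"][0] == pytest.approx(fit1["coef"][0] / 10, rel=1e-6)
        assert fit2["p"][0] == pytest.approx(fit1["p"][0], abs=1e-8)

    def test_planted_log_hazard_recovered(self):
        lp = np.concatenate([np.zeros(200), np.full(200, np.log(2.0))])
        frame = simulate_survival_endpoints(lp, 0.02, 0.3, 120.0, seed=42)
        df = frame.assign(x=(lp > 0).astype(float))
        fit = sv.cox_model(df, "time", "event", ["x"])
        assert 1.6 <= fit["hr"][0] <= 2.5

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2, 3, 4], "e": [1, 1, 1, 1],
                           "x": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            sv.cox_model(df, "t", "e", ["x"])


class TestConcordance:
    def test_perfect_discrimination(self):
        assert sv.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_three_pair_enumeration(self):
        # pairs: (1,2) conc, (1,3) conc, (2,3) disc -> 2/3
        assert sv.concordance_index([3, 1, 2], [1, 2, 3], [1, 1, 1]) \
            == pytest.approx(2 / 3)

    def test_random_marker_near_half(self, rng):
        t = rng.exponential(10, size=2000)
        risk = rng.normal(size=2000)
        c = sv.concordance_index(risk, t, np.ones(2000, dtype=int))
        assert c == pytest.approx(0.5, abs=0.05)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index as ll_c
        t = rng.exponential(10, size=100)
        e = rng.integers(0, 2, size=100)
        e[:5] = 1
        risk = rng.normal(size=100)
        assert sv.concordance_index(risk, t, e) == pytest.approx(
            ll_c(t, -risk, e), abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            sv.concordance_index([1, 2], [5, 6], [0, 0])


class TestIpcw:
    def test_no_censoring_gives_unit_weights(self):
        w = sv.ipcw_weights([1, 2, 3], [1, 1, 1], t=2.5)
        np.testing.assert_allclose(w, 1.0)

    def test_censored_before_horizon_gets_zero(self):
        w = sv.ipcw_weights([1, 2, 3, 4], [1, 0, 1, 1], t=3.5)
        assert w[1] == 0.0

    def test_hand_computed_censoring_km(self):
        # censoring at t=2 with risk set {2,3,4}: G drops to 2/3 there.
        # weights at t=3.5: event@1 -> 1/G(1-)=1; censored@2 -> 0;
        # event@3 -> 1/G(3-)=3/2; survivor@4 -> 1/G(3.5)=3/2.
        w = sv.ipcw_weights([1, 2, 3, 4], [1, 0, 1, 1], t=3.5)
        np.testing.assert_allclose(w, [1.0, 0.0, 1.5, 1.5])

    def test_matches_sksurv_censoring_distribution(self, rng):
        from sksurv.nonparametric import CensoringDistributionEstimator
        t = np.unique(rng.exponential(10, size=60))  # tie-free
        e = rng.integers(0, 2, size=len(t))
        e[-1] = 1  # keep G positive at the horizon
        cens = CensoringDistributionEstimator().fit(
            np.array(list(zip(e.astype(bool), t)),
                     dtype=[("event", bool), ("time", float)]))
        G = sv.censoring_survival(t, e)
        grid = np.quantile(t, [0.1, 0.4, 0.7])
        np.testing.assert_allclose(G.evaluate(grid),
                                   cens.predict_proba(grid), atol=1e-10)


class TestBrier:
    def test_perfect_forecast_zero(self):
        t = np.array([1.0, 2, 5, 6])
        e = np.ones(4, dtype=int)
        pred = np.array([0.0, 0.0, 1.0, 1.0])  # deaths before t=3 vs after
        assert sv.brier_score(pred, t, e, t=3.0) == 0.0

    def test_constant_half_prediction(self):
        t = np.array([1.0, 2, 5, 6])
        assert sv.brier_score([0.5] * 4, t, np.ones(4, dtype=int), 3.0) \
            == pytest.approx(0.25, abs=1e-15)

    def test_no_censoring_equals_plain_mse(self, rng):
        n = 50
        t = rng.exponential(10, size=n)
        e = np.ones(n, dtype=int)
        pred = rng.uniform(size=n)
        horizon = float(np.median(t))
        plain = np.mean(np.where(t <= horizon, (0 - pred) ** 2,
                                 (1 - pred) ** 2))
        assert sv.brier_score(pred, t, e, horizon) \
            == pytest.approx(plain, abs=1e-12)

    def test_ibs_integrates_to_quarter_for_constant_half(self, rng):
        # BS(t)=0.25 for all t without censoring -> IBS = 0.25
        t = rng.exponential(10, size=40)
        e = np.ones(40, dtype=int)
        grid = sv.make_prediction_grid(t, e, float(np.max(t)))
        sm = np.full((40, len(grid)), 0.5)
        ibs = sv.integrated_brier_score(sm, grid, t, e)
        # trapezoid starts from BS(0)=0, so the first panel dips below 0.25
        assert 0.2 < ibs <= 0.25

    def test_matches_sksurv_brier(self, rng):
        from sksurv.metrics import brier_score as sks_brier
        t = np.unique(rng.exponential(12, size=80))
        e = rng.integers(0, 2, size=len(t))
        e[-1] = 1
        pred = rng.uniform(size=len(t))
        horizon = float(np.quantile(t, 0.5))
        y = np.array(list(zip(e.astype(bool), t)),
                     dtype=[("event", bool), ("time", float)])
        _, ref = sks_brier(y, y, pred, horizon)
        assert sv.brier_score(pred, t, e, horizon) \
            == pytest.approx(ref[0], abs=1e-10)


class TestTimeDependentAuc:
    def test_perfect_and_reversed_separation(self):
        t = np.array([1.0, 2, 8, 9])
        e = np.ones(4, dtype=int)
        assert sv.time_dependent_auc([4, 3, 2, 1], t, e, 5.0) == 1.0
        assert sv.time_dependent_auc([1, 2, 3, 4], t, e, 5.0) == 0.0

    def test_equals_mann_whitney_without_censoring(self, rng):
        n = 60
        t = rng.exponential(10, size=n)
        e = np.ones(n, dtype=int)
        marker = rng.normal(size=n)
        horizon = float(np.median(t))
        # brute-force pair enumeration
        cases = np.where(t <= horizon)[0]
        controls = np.where(t > horizon)[0]
        wins = sum((marker[i] > marker[j]) + 0.5 * (marker[i] == marker[j])
                   for i in cases for j in controls)
        mw = wins / (len(cases) * len(controls))
        assert sv.time_dependent_auc(marker, t, e, horizon) \
            == pytest.approx(mw, abs=1e-12)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="t=0.5"):
            sv.time_dependent_auc([1, 2], [1.0, 2.0], [1, 1], 0.5)


class TestNriIdi:
    def test_identical_models_give_zero(self, rng):
        t = rng.exponential(10, size=30)
        e = np.ones(30, dtype=int)
        risk = rng.uniform(size=30)
        horizon = float(np.median(t))
        assert sv.nri(risk, risk, t, e, horizon) == 0.0
        assert sv.idi(risk, risk, t, e, horizon) == 0.0

    def test_idi_definitional_maximum(self):
        t = np.array([1.0, 2, 8, 9])
        e = np.ones(4, dtype=int)
        old = np.full(4, 0.5)
        new = np.array([1.0, 1.0, 0.0, 0.0])
        assert sv.idi(old, new, t, e, 5.0) == pytest.approx(1.0)

    def test_nri_definitional_maximum(self):
        t = np.array([1.0, 2, 8, 9])
        e = np.ones(4, dtype=int)
        old = np.full(4, 0.5)
        new = np.array([0.9, 0.9, 0.1, 0.1])  # events up, non-events down
        assert sv.nri(old, new, t, e, 5.0) == pytest.approx(2.0)


class TestMonotoneInvariance:
    def test_c_index_and_auc_invariant_under_monotone_maps(self, rng):
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        e[:5] = 1
        risk = rng.normal(size=80)
        horizon = float(np.quantile(t[e == 1], 0.6))
        base_c = sv.concordance_index(risk, t, e)
        base_auc = sv.time_dependent_auc(risk, t, e, horizon)
        for f in (lambda x: np.exp(0.7 * x), lambda x: x ** 3 + 5 * x,
                  lambda x: np.arctan(x)):
            assert sv.concordance_index(f(risk), t, e) \
                == pytest.approx(base_c, abs=1e-12)
            assert sv.time_dependent_auc(f(risk), t, e, horizon) \
                == pytest.approx(base_auc, abs=1e-12)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        point, lo, hi = sv.bootstrap_ci(lambda idx: 0.7, n=30, B=200, seed=1)
        assert (point, lo, hi) == (0.7, 0.7, 0.7)

    def test_same_seed_identical_interval(self, rng):
        x = rng.normal(size=40)
        fn = lambda idx: float(np.mean(x[idx]))
        assert sv.bootstrap_ci(fn, 40, B=200, seed=5) \
            == sv.bootstrap_ci(fn, 40, B=200, seed=5)

    def test_failure_tally_raises(self):
        def bad(idx):
            # identity index (the point estimate) is fine; resamples with
            # repeated patients fail
            if len(np.unique(idx)) < len(idx):
                raise ValueError("nope")
            return 1.0
        with pytest.raises(RuntimeError, match="resamples"):
            sv.bootstrap_ci(bad, n=10, B=100, seed=0)


class TestSimulateSurvival:
    def test_exponential_median_closed_form(self):
        frame = simulate_survival_endpoints(np.zeros(50_000), 0.01, 0.0,
                                            5000.0, seed=7)
        med = float(np.median(frame["time"]))
        assert med == pytest.approx(np.log(2) / 0.01, rel=0.03)

    def test_forced_administrative_censoring(self):
        # horizon far below any plausible event time: all censored at horizon
        frame = simulate_survival_endpoints(np.zeros(200), 1e-6, 0.0, 0.001,
                                            seed=1)
        assert (frame["event"] == 0).all()
        assert (frame["time"] > 0).all()

    def test_censor_fraction_near_target(self):
        frame = simulate_survival_endpoints(np.zeros(20_000), 0.02, 0.35,
                                            120.0, seed=3)
        assert float((frame["event"] == 0).mean()) \
            == pytest.approx(0.35, abs=0.02)

    def test_censoring_mechanism_independent_of_predictor(self):
        # the censoring-time distribution must not depend on the linear
        # predictor: the reverse-KM censoring curves of the low- and
        # high-risk strata coincide (both estimate the same G)
        lp = np.repeat([-0.5, 0.5], 20_000)
        frame = simulate_survival_endpoints(lp, 0.02, 0.4, 120.0, seed=9)
        t = frame["time"].to_numpy()
        e = frame["event"].to_numpy()
        lo, hi = lp < 0, lp > 0
        G_lo = sv.censoring_survival(t[lo], e[lo])
        G_hi = sv.censoring_survival(t[hi], e[hi])
        for horizon in (30.0, 60.0, 90.0):
            assert G_lo.evaluate(horizon) \
                == pytest.approx(G_hi.evaluate(horizon), abs=0.03)

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival_endpoints([0.0, np.inf], 0.01, 0.1, 100.0)
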