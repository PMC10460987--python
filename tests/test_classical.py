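import numpy as np
import pandas as pd
import pytest

from mcisurv.classical import (
    bh_adjust,
    breslow_baseline,
    fit_cox_elasticnet,
    hazard_ratio,
    kaplan_meier,
    predict_cox_survival,
    survival_difference_at_time,
)


class TestKaplanMeier:
    def test_no_events(self):
        km = kaplan_meier([5, 10, 15], [False, False, False])
        assert np.allclose(km.survival, 1.0)

    def test_hand_product_limit(self):
        km = kaplan_meier([5, 10, 15], [True, False, True])
        assert km.survival_at(5) == pytest.approx(2 / 3)
        assert km.survival_at(10) == pytest.approx(2 / 3)
        assert km.survival_at(15) == pytest.approx(0.0)

    def test_uncensored_equals_empirical(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1, 100, size=40)
        km = kaplan_meier(times, np.ones(40, dtype=bool))
        for t in (10, 30, 60, 90):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        times = rng.integers(1, 60, size=80).astype(float)
        events = rng.random(80) < 0.5
        km = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in (5, 20, 40, 59):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_band_contains_estimate(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(1, 100, 60)
        events = rng.random(60) < 0.6
        km = kaplan_meier(times, events)
        inside = (km.ci_lower <= km.survival + 1e-12) & (km.survival <= km.ci_upper + 1e-12)
        assert inside.all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestSurvivalDifference:
    def test_identical_samples(self):
        times = [5, 10, 20, 30, 40]
        events = [True, False, True, False, True]
        res = survival_difference_at_time(times, events, times, events, 25)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_degenerate_survival_reported(self):
        res = survival_difference_at_time(
            [5, 6, 12, 12], [True, True, False, False],
            [12, 12, 12, 12], [False, False, False, False], 10,
        )
        assert np.isnan(res["statistic"]) and "note" in res

    def test_hand_evaluated_delta_method_formula(self):
        """Statistic equals a from-scratch evaluation of the log(-log) formula."""
        ta = np.array([5.0, 6.0, 15.0, 30.0, 50.0, 50.0, 50.0, 50.0])
        ea = np.array([1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
        tb = np.array([8.0, 20.0, 25.0, 40.0, 50.0, 50.0, 50.0, 50.0])
        eb = np.array([1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        t = 35.0
        res = survival_difference_at_time(ta, ea, tb, eb, t)
        # group A: events at 5 (n=8), 6 (n=7), 30 (n=5)
        sa = (7 / 8) * (6 / 7) * (4 / 5)
        siga = 1 / (8 * 7) + 1 / (7 * 6) + 1 / (5 * 4)
        # group B: events at 8 (n=8), 25 (n=6)
        sb = (7 / 8) * (5 / 6)
        sigb = 1 / (8 * 7) + 1 / (6 * 5)
        num = (np.log(-np.log(sa)) - np.log(-np.log(sb))) ** 2
        den = siga / np.log(sa) ** 2 + sigb / np.log(sb) ** 2
        assert res["statistic"] == pytest.approx(num / den, abs=1e-12)
        assert res["S_A"] == pytest.approx(sa) and res["S_B"] == pytest.approx(sb)

    def test_close_to_lifelines_fixed_point_test(self):
        """Agrees with the lifelines test up to its interpolation of the
        cumulative variance between event times."""
        from lifelines import KaplanMeierFitter
        from lifelines.statistics import survival_difference_at_fixed_point_in_time_test

        rng = np.random.default_rng(3)
        ta = rng.uniform(1, 100, 40); ea = rng.random(40) < 0.5
        tb = rng.uniform(1, 80, 40); eb = rng.random(40) < 0.7
        res = survival_difference_at_time(ta, ea, tb, eb, 30.0)
        kma = KaplanMeierFitter().fit(ta, ea)
        kmb = KaplanMeierFitter().fit(tb, eb)
        ll = survival_difference_at_fixed_point_in_time_test(30.0, kma, kmb)
        assert res["statistic"] == pytest.approx(ll.test_statistic, rel=0.25)

    def test_statistic_grows_with_sample_size(self):
        ta = [5.0, 6.0] + [50.0] * 8
        ea = [True, True] + [False] * 8
        tb = [8.0] + [50.0] * 9
        eb = [True] + [False] * 9
        small = survival_difference_at_time(ta, ea, tb, eb, 12.0)
        big = survival_difference_at_time(ta * 2, ea * 2, tb * 2, eb * 2, 12.0)
        assert big["statistic"] > small["statistic"]


def _breslow_partial_loglik(beta, group, times, events):
    """Direct evaluation of the Breslow partial log-likelihood (oracle)."""
    ll = 0.0
    for t in np.unique(times[events]):
        d_set = events & (times == t)
        at_risk = times >= t
        ll += beta * group[d_set].sum()
        ll -= d_set.sum() * np.log(np.exp(beta * group[at_risk]).sum())
    return ll


class TestHazardRatio:
    def test_identical_outcomes_give_unit_hr(self):
        times = np.r_[[5, 10, 15, 20, 30], [5, 10, 15, 20, 30]].astype(float)
        events = np.r_[[1, 0, 1, 1, 0], [1, 0, 1, 1, 0]].astype(bool)
        group = np.r_[np.ones(5), np.zeros(5)]
        res = hazard_ratio(group, times, events)
        assert res["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        times = rng.permutation(np.arange(1.0, 21.0))  # no ties
        group = (np.arange(20) < 10).astype(float)
        events = rng.random(20) < 0.7
        res = hazard_ratio(group, times, events)
        grid = np.linspace(res["beta"] - 0.5, res["beta"] + 0.5, 2001)
        lls = [_breslow_partial_loglik(b, group, times, events) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert res["beta"] == pytest.approx(beta_grid, abs=1e-3)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(1, 50, 30)
        events = rng.random(30) < 0.6
        group = (rng.random(30) < 0.5).astype(float)
        a = hazard_ratio(group, times, events)
        b = hazard_ratio(1 - group, times, events)
        assert a["hr"] == pytest.approx(1 / b["hr"], rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            hazard_ratio([0, 1], [5.0, 6.0], [False, False])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _survival_fixture(seed=6, n=120, p=4, beta=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else beta
    lam = 40 * np.exp(-x @ beta)
    t_event = rng.exponential(lam)
    cens = rng.uniform(10, 120, n)
    times = np.minimum(t_event, cens)
    events = t_event <= cens
    cols = [f"f{i}" for i in range(p)]
    return (
        pd.DataFrame(x, columns=cols),
        pd.DataFrame({"time_months": times, "event": events}),
    )


class TestCoxElasticNet:
    def test_huge_penalty_shrinks_to_null(self):
        beta = np.array([1.0, 0.0, 0.0, 0.0])
        x, y = _survival_fixture(beta=beta)
        model = fit_cox_elasticnet(x[:80], y[:80], x[80:], y[80:],
                                   penalties=(1e4,), l1_ratios=(0.5,))
        assert np.abs(model.coef).max() < 1e-6

    def test_strong_covariate_sign_recovery(self):
        beta = np.array([1.5, 0.0, 0.0, 0.0])
        x, y = _survival_fixture(beta=beta, n=300)
        model = fit_cox_elasticnet(x[:200], y[:200], x[200:], y[200:],
                                   penalties=(1e-3,), l1_ratios=(0.5,))
        assert model.coef[0] > 0.5  # higher f0 -> shorter survival -> positive beta
        assert model.val_ci > 0.6

    def test_single_grid_point_returned(self):
        x, y = _survival_fixture()
        model = fit_cox_elasticnet(x[:80], y[:80], x[80:], y[80:],
                                   penalties=(0.05,), l1_ratios=(0.9,))
        assert model.penalty == 0.05 and model.l1_ratio == 0.9


class TestPredictCoxSurvival:
    def test_zero_linear_predictor_gives_baseline(self):
        x, y = _survival_fixture()
        model = fit_cox_elasticnet(x[:80], y[:80], x[80:], y[80:],
                                   penalties=(1e4,), l1_ratios=(0.5,))
        curves = predict_cox_survival(model, x[80:])
        baseline = np.exp(-model.cumulative_hazard())
        assert np.allclose(curves, baseline[None, :])

    def test_proportional_hazards_ordering(self):
        beta = np.array([1.0, -0.5, 0.0, 0.0])
        x, y = _survival_fixture(beta=beta, n=200)
        model = fit_cox_elasticnet(x[:150], y[:150], x[150:], y[150:],
                                   penalties=(1e-3,), l1_ratios=(0.5,))
        curves = predict_cox_survival(model, x[150:])
        lp = model.linear_predictor(x[150:])
        i, j = int(np.argmin(lp)), int(np.argmax(lp))
        assert (curves[i] >= curves[j] - 1e-12).all()
        assert np.allclose(curves[:, 0], 1.0)

    def test_breslow_against_brute_force(self):
        """Baseline cumulative hazard equals the hand Breslow sum."""
        rng = np.random.default_rng(7)
        times = rng.permutation(np.arange(1.0, 13.0))
        events = np.ones(12, dtype=bool)
        lp = rng.normal(size=12)
        bt, bh = breslow_baseline(times, events, lp)
        risk = np.exp(lp)
        expected = []
        total = 0.0
        for t in np.sort(times):
            total += 1.0 / risk[times >= t].sum()
            expected.append(total)
        assert np.allclose(bh, expected)
        assert (np.diff(bh) >= 0).all()
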