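import numpy as np
import pytest

from mcisurv.evaluation import (
    MONTH_GRID,
    bootstrap_mean_band,
    brier_score,
    censoring_survival,
    concordance_index,
    evaluate_predictions,
    integrated_brier_score,
    marginal_km_curves,
    permutation_null_ci,
    truncate_and_interpolate,
)


def brute_force_ci(times, events, risk):
    conc = 0.0
    comp = 0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[j] > times[i]:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp


class TestConcordance:
    def test_perfect_and_reversed_ranking(self):
        assert concordance_index([5, 10], [True, True], [0.9, 0.1]) == 1.0
        assert concordance_index([5, 10], [True, True], [0.1, 0.9]) == 0.0

    def test_brute_force_oracle_small_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 26)
            times = rng.integers(1, 40, n).astype(float)
            events = rng.random(n) < 0.6
            risk = rng.normal(size=n).round(1)  # coarse -> risk ties occur
            if not (events & (times < times.max())).any():
                continue
            assert concordance_index(times, events, risk) == pytest.approx(
                brute_force_ci(times, events, risk), abs=1e-15
            )

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(1)
        times = rng.permutation(np.arange(1.0, 41.0))  # no time ties
        events = rng.random(40) < 0.5
        risk = rng.normal(size=40)
        ours = concordance_index(times, events, risk)
        theirs = concordance_index_censored(events, times, risk)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([5, 5], [False, False], [0.1, 0.2])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(1, 100, 200)
        events = rng.random(200) < 0.4
        mu, se = permutation_null_ci(times, events, rng.normal(size=200),
                                     n_perm=200, seed=3)
        assert abs(mu - 0.5) < 3 * se


class TestCensoringSurvival:
    def test_no_censoring(self):
        g = censoring_survival([5, 10, 15], [True, True, True])
        assert np.allclose(g.survival, 1.0)

    def test_point_mass(self):
        g = censoring_survival([50, 50, 50], [False, False, False])
        assert g.at(40) == 1.0
        assert g.at(50) == 0.0
        assert g.at(50, left=True) == 1.0

    def test_hand_product_limit_flipped(self):
        # times 2(c), 4(e), 6(c), 8(c): censor hazards 1/4, then 1/2, then 1/1
        g = censoring_survival([2, 4, 6, 8], [False, True, False, False])
        assert g.at(2) == pytest.approx(3 / 4)
        assert g.at(6) == pytest.approx(3 / 8)
        assert g.at(8) == pytest.approx(0.0)

    def test_events_precede_censorings_at_ties(self):
        # at t=5: one event, one censoring -> censor at-risk excludes the event
        g = censoring_survival([5, 5, 10], [True, False, False])
        assert g.at(5) == pytest.approx(1 - 1 / 2)


def _curves_const(n, value):
    return np.full((n, len(MONTH_GRID)), value, dtype=float)


class TestBrierScore:
    def test_perfect_oracle_zero(self):
        times = np.array([10.0, 30.0, 80.0, 90.0])
        events = np.array([True, True, False, False])
        g = censoring_survival(times, events)
        curves = np.ones((4, len(MONTH_GRID)))
        for i, t in enumerate(times):
            if events[i]:
                curves[i, MONTH_GRID >= t] = 0.0
        assert brier_score(times, events, curves, 48.0, g) == pytest.approx(0.0)

    def test_constant_half_predictor_uncensored(self):
        times = np.array([10.0, 30.0, 80.0, 90.0])
        events = np.ones(4, dtype=bool)
        g = censoring_survival(times, events)
        assert brier_score(times, events, _curves_const(4, 0.5), 48.0, g) == pytest.approx(0.25)

    def test_hand_ipcw_fixture(self):
        """Six-subject censored fixture evaluated by hand to 1e-12."""
        times = np.array([10.0, 20.0, 30.0, 40.0, 60.0, 90.0])
        events = np.array([True, False, True, False, True, False])
        g = censoring_survival(times, events)
        s_hat = 0.7
        curves = _curves_const(6, s_hat)
        t = 48.0
        # censoring KM: censored at 20 (risk 5) -> 4/5; at 40 (risk 3) -> 4/5*2/3
        g10 = 1.0            # G(10-)
        g30 = 4 / 5          # G(30-)
        g48 = 4 / 5 * 2 / 3  # G(48)
        expected = (
            s_hat**2 / g10          # event at 10
            + s_hat**2 / g30        # event at 30
            + (1 - s_hat) ** 2 / g48  # survivor at 60
            + (1 - s_hat) ** 2 / g48  # survivor at 90
        ) / 6
        assert brier_score(times, events, curves, t, g) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_mse_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(1, 100, 50)
        events = np.ones(50, dtype=bool)
        g = censoring_survival(times, events)
        curves = np.clip(rng.random((50, len(MONTH_GRID))), 0, 1)
        curves = np.sort(curves, axis=1)[:, ::-1]
        for t in (24.0, 48.0, 108.0):
            col = int(t)
            mse = np.mean((( times > t).astype(float) - curves[:, col]) ** 2)
            assert brier_score(times, events, curves, t, g) == pytest.approx(mse, abs=1e-12)


class TestIntegratedBrier:
    def test_flat_integrand(self):
        times = np.array([10.0, 30.0, 80.0, 90.0])
        events = np.ones(4, dtype=bool)
        g = censoring_survival(times, events)
        ibs = integrated_brier_score(times, events, _curves_const(4, 0.5), g)
        assert ibs == pytest.approx(0.25)

    def test_hand_trapezoid(self):
        # direct check of the quadrature: BS = (0, 0.1, 0.2) at (24, 48, 108)
        bs = np.array([0.0, 0.1, 0.2])
        ts = np.array([24.0, 48.0, 108.0])
        expected = (0.05 * 24 + 0.15 * 60) / 84
        assert np.trapezoid(bs, ts) / 84 == pytest.approx(expected)
        assert expected == pytest.approx(0.12142857142857143)

    def test_order_invariance_and_guard(self):
        times = np.array([10.0, 30.0, 80.0, 90.0])
        events = np.ones(4, dtype=bool)
        g = censoring_survival(times, events)
        curves = _curves_const(4, 0.6)
        a = integrated_brier_score(times, events, curves, g, eval_times=(24, 48, 108))
        b = integrated_brier_score(times, events, curves, g, eval_times=(108, 24, 48))
        assert a == b
        with pytest.raises(ValueError):
            integrated_brier_score(times, events, curves, g, eval_times=(48,))


class TestTruncateAndInterpolate:
    def test_noop_when_range_covered(self):
        rng = np.random.default_rng(5)
        curves = np.sort(rng.random((3, len(MONTH_GRID))), axis=1)[:, ::-1]
        out, grid = truncate_and_interpolate(curves, 108.0)
        assert np.array_equal(out, curves)
        assert np.array_equal(grid, MONTH_GRID)

    def test_boundary_replacement(self):
        curves = np.linspace(1.0, 0.4, len(MONTH_GRID))[None, :]
        out, grid = truncate_and_interpolate(curves, 90.0)
        assert np.allclose(out[0, MONTH_GRID > 90], out[0, 90])
        assert grid.max() == 90.0

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            steps = rng.random(len(MONTH_GRID) - 1) * 0.02
            curve = np.concatenate([[1.0], 1.0 - np.cumsum(steps)]).clip(0, 1)
            out, _ = truncate_and_interpolate(curve[None, :], 77.5)
            assert (np.diff(out[0]) <= 1e-10).all()

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            truncate_and_interpolate(np.ones((1, len(MONTH_GRID))), 0.0)


class TestBootstrapBand:
    def test_identical_curves_zero_width(self):
        curves = np.tile(np.linspace(1, 0.5, 109), (5, 1))
        band = bootstrap_mean_band(curves, n_boot=200, seed=0)
        assert np.allclose(band["lower"], band["upper"])

    def test_band_brackets_mean(self):
        rng = np.random.default_rng(7)
        curves = np.sort(rng.random((40, 109)), axis=1)[:, ::-1]
        band = bootstrap_mean_band(curves, n_boot=500, seed=1)
        assert (band["lower"] <= band["mean"] + 1e-12).all()
        assert (band["mean"] <= band["upper"] + 1e-12).all()

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        base = np.sort(rng.random((400, 109)), axis=1)[:, ::-1]
        w_small = np.mean(
            bootstrap_mean_band(base[:100], 500, seed=2)["upper"]
            - bootstrap_mean_band(base[:100], 500, seed=2)["lower"]
        )
        w_big = np.mean(
            bootstrap_mean_band(base, 500, seed=3)["upper"]
            - bootstrap_mean_band(base, 500, seed=3)["lower"]
        )
        ratio = w_small / w_big
        assert 1.5 < ratio < 2.7  # ~ sqrt(4) = 2

    def test_determinism_and_guard(self):
        rng = np.random.default_rng(9)
        curves = rng.random((10, 109))
        a = bootstrap_mean_band(curves, 100, seed=5)
        b = bootstrap_mean_band(curves, 100, seed=5)
        assert np.array_equal(a["lower"], b["lower"])
        with pytest.raises(ValueError):
            bootstrap_mean_band(curves[:1], 100, seed=5)


class TestEvaluatePredictions:
    def test_report_structure_and_km_reference(self):
        rng = np.random.default_rng(10)
        tr_times = rng.uniform(1, 108, 100)
        tr_events = rng.random(100) < 0.4
        te_times = rng.uniform(1, 100, 50)
        te_events = rng.random(50) < 0.4
        curves = marginal_km_curves(tr_times, tr_events, 50)
        rep = evaluate_predictions(curves, te_times, te_events, tr_times, tr_events)
        assert set(rep["ci"]) == {24.0, 48.0, 108.0}
        assert rep["ibs"] >= 0
        assert rep["n"] == 50 and rep["events"] + rep["censored"] == 50
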