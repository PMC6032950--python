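import numpy as np
import pytest
from scipy import stats

from labourprogress import markov as mk
from labourprogress.markov import (
    BIRTH_STATE,
    DataError,
    PercentileCurve,
    ProgressiveMarkovModel,
    ProgressiveModel,
    build_generator,
    crossed_percentile_curve,
    first_passage_quantile,
    fit_rates,
    panel_log_likelihood,
    percentile_curve,
    transition_matrix,
)


class TestGenerator:
    def test_single_state(self):
        Q = build_generator([2.0])
        assert np.array_equal(Q, [[-2.0, 2.0], [0.0, 0.0]])

    def test_structure_and_conservation(self):
        rates = [0.5, 1.5, 0.9]
        Q = build_generator(rates)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(np.diag(Q, k=1), rates)
        assert np.allclose(np.tril(Q, k=-1), 0.0)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_generator([1.0, 0.0])


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        Q = build_generator([1.0, 2.0])
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(3))

    def test_single_state_staying_probability(self):
        P = transition_matrix(build_generator([1.0]), 1.0)
        assert P[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            transition_matrix(build_generator([1.0]), -0.1)

    def test_rows_stochastic_and_upper_triangular(self):
        Q = build_generator([0.7, 1.3, 2.1, 0.4])
        for t in (0.1, 1.0, 7.5):
            P = transition_matrix(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= -1e-12) and np.all(P <= 1.0 + 1e-12)
            assert np.allclose(np.tril(P, k=-1), 0.0, atol=1e-12)

    def test_absorption_matches_hypoexponential_cdf(self):
        """Matrix exponential agrees with the closed-form two-rate CDF."""
        lam1, lam2 = 0.8, 1.7
        Q = build_generator([lam1, lam2])
        for t in (0.2, 1.0, 3.0, 9.0):
            closed = 1 - (lam2 * np.exp(-lam1 * t) - lam1 * np.exp(-lam2 * t)) / (
                lam2 - lam1
            )
            assert transition_matrix(Q, t)[0, -1] == pytest.approx(closed, abs=1e-8)

    def test_chapman_kolmogorov(self):
        Q = build_generator([0.6, 1.2, 0.9])
        for s, t in ((0.5, 1.5), (2.0, 3.0)):
            left = transition_matrix(Q, s + t)
            right = transition_matrix(Q, s) @ transition_matrix(Q, t)
            assert np.allclose(left, right, atol=1e-10)

    def test_uniformization_handles_tied_rates(self):
        lam = np.array([1.3, 1.3, 1.3, 1.3])
        ts = np.array([0.0, 0.4, 2.0, 11.0])
        expected = np.array(
            [transition_matrix(build_generator(lam), t)[0, -1] for t in ts]
        )
        assert np.allclose(mk._uniformized_cdf(lam, ts), expected, atol=1e-10)
        # the dispatcher must route tied rates away from the closed form
        assert np.allclose(mk._hypoexp_cdf(lam, ts), expected, atol=1e-10)


class TestPanelLikelihood:
    def test_single_staying_pair(self):
        model = ProgressiveModel((9, 10), np.array([1.0, 1.0]))
        ll = panel_log_likelihood(model, [np.array([[0.0, 9.0], [1.0, 9.0]])])
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_additivity_over_series(self):
        model = ProgressiveModel((8, 9, 10), np.array([0.7, 1.1, 2.0]))
        s1 = np.array([[0.0, 8.0], [2.0, 9.0]])
        s2 = np.array([[0.0, 9.0], [1.5, BIRTH_STATE]])
        assert panel_log_likelihood(model, [s1, s2]) == pytest.approx(
            panel_log_likelihood(model, [s1]) + panel_log_likelihood(model, [s2])
        )

    def test_regression_identifies_series(self):
        good = np.array([[0.0, 5.0], [1.0, 6.0]])
        bad = np.array([[0.0, 7.0], [1.0, 6.0]])
        with pytest.raises(DataError, match="w42"):
            panel_log_likelihood(
                ProgressiveModel((5, 6, 7, 8, 9, 10), np.ones(6)),
                {"ok": good, "w42": bad},
            )

    def test_fully_observed_single_state_mle_is_closed_form(self, rng):
        """With the state watched up to the sojourn's end and absorption
        confirmed immediately after, the panel MLE collapses to the
        exponential closed form: transitions over time at risk."""
        lam_true = 1.4
        eps = 1e-4
        sojourns = rng.exponential(1.0 / lam_true, size=400)
        series = [
            np.array([[0.0, 10.0], [s, 10.0], [s + eps, BIRTH_STATE]])
            for s in sojourns
        ]
        closed_form = 1.0 / np.mean(sojourns)
        fit = fit_rates(series, min_transitions=5, highest_required_state=10)
        assert fit.model.rate_of(10) == pytest.approx(closed_form, rel=1e-3)
        assert fit.n_transitions_used == 400


class TestFit:
    def test_insufficient_transitions_names_state(self):
        series = [np.array([[0.0, 4.0], [1.0, 5.0], [2.0, BIRTH_STATE]])] * 6
        # state 5..10 spanned 6 times, but requiring 10 per state must fail
        with pytest.raises(mk.FitError, match="state"):
            fit_rates(series, min_transitions=10)

    def test_init_at_truth_is_stable(self, rng):
        true = np.array([1.0, 1.5, 2.0])
        model = ProgressiveModel((8, 9, 10), true)
        series = []
        for _ in range(300):
            t, s, obs = 0.0, 8, [(0.0, 8.0)]
            for state in (8, 9, 10):
                t += rng.exponential(1.0 / true[state - 8])
                obs.append((t, state + 1 if state < 10 else BIRTH_STATE))
            series.append(np.array(obs))
        fit = fit_rates(series, init_rates=true, highest_required_state=8, n_starts=1)
        assert fit.converged
        # the optimum must not be worse than the truth
        assert fit.log_likelihood >= panel_log_likelihood(model, series) - 1e-6


class TestQuantiles:
    def test_exponential_median(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.ones(7))
        assert first_passage_quantile(model, 5, 0.5) == pytest.approx(
            np.log(2), abs=1e-8
        )

    def test_erlang_median(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.ones(7))
        assert first_passage_quantile(model, 6, 0.5) == pytest.approx(
            stats.gamma.ppf(0.5, a=2), abs=1e-6
        )

    def test_quantiles_increase_in_p(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.array([0.9, 1.1, 1.4, 1.2, 2.0, 1.7, 2.4]))
        qs = [first_passage_quantile(model, 8, p) for p in (0.5, 0.6, 0.9, 0.95)]
        assert np.all(np.diff(qs) > 0)

    def test_invalid_level_rejected(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.ones(7))
        with pytest.raises(ValueError, match="quantile level"):
            first_passage_quantile(model, 6, 1.0)


class TestPercentileCurves:
    def test_equal_rate_curve_is_erlang_quantiles(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.ones(7))
        curve = percentile_curve(model, "3N", 50)
        for d in range(5, 11):
            assert curve.points[d] == pytest.approx(
                stats.gamma.ppf(0.5, a=d - 4), abs=1e-6
            )
        assert np.all(np.diff([curve.points[d] for d in range(5, 11)]) > 0)

    def test_doubling_rates_halves_times(self):
        slow = percentile_curve(
            ProgressiveModel(tuple(range(4, 11)), np.full(7, 0.8)), "s", 90
        )
        fast = percentile_curve(
            ProgressiveModel(tuple(range(4, 11)), np.full(7, 1.6)), "f", 90
        )
        for d in range(5, 11):
            assert fast.points[d] == pytest.approx(slow.points[d] / 2, abs=1e-6)


class TestCurveCrossing:
    @pytest.fixture()
    def curve(self):
        model = ProgressiveModel(tuple(range(4, 11)), np.ones(7))
        return percentile_curve(model, "1N", 50)

    def test_boundary_equality_not_crossed(self, curve):
        exams = [(0.0, 4), (curve.points[8], 8)]
        assert crossed_percentile_curve(exams, curve).crossed is False

    def test_slower_than_percentile_crossed(self, curve):
        exams = [(0.0, 4), (curve.points[8] + 0.1, 8)]
        res = crossed_percentile_curve(exams, curve)
        assert res.crossed and res.first_crossing_exam_index == 1

    def test_anchor_above_4cm_offsets_by_curve_time(self, curve):
        # anchored at 6 cm: elapsed time is measured against q(6 -> d)
        exams = [(0.0, 6), (curve.points[9] - curve.points[6], 9)]
        assert crossed_percentile_curve(exams, curve).crossed is False
        exams_slow = [(0.0, 6), (curve.points[9] - curve.points[6] + 0.05, 9)]
        assert crossed_percentile_curve(exams_slow, curve).crossed is True

    def test_no_anchor_not_evaluable(self, curve):
        assert crossed_percentile_curve([(0.0, 2), (1.0, 3)], curve) is None

    def test_crossing_higher_percentile_implies_lower(self, rng):
        """Crossers of the 95th-percentile curve are a subset of crossers
        of the 50th, checked by brute force over simulated exam series."""
        from labourprogress.synthetic import simulate_trajectory, observe_panel

        model = ProgressiveModel(tuple(range(4, 11)), np.full(7, 1.2))
        c50 = percentile_curve(model, "x", 50)
        c95 = percentile_curve(model, "x", 95)
        rates = {s: 1.0 for s in range(2, 11)}
        for _ in range(200):
            path = simulate_trajectory(rates, int(rng.integers(2, 7)), rng)
            exams = observe_panel(path, lambda r: int(r.integers(1, 5)), rng)
            r95 = crossed_percentile_curve(exams, c95)
            r50 = crossed_percentile_curve(exams, c50)
            if r95 is not None and r95.crossed:
                assert r50.crossed


class TestEstimator:
    def test_fitted_attributes_and_reuse(self, rng):
        true = {s: 1.0 for s in range(4, 11)}
        from labourprogress.synthetic import simulate_trajectory

        series = []
        for _ in range(400):
            path = simulate_trajectory(true, 4, rng)
            obs = [(t, min(s, 10)) for s, t in path[:-1]] + [
                (path[-1][1], BIRTH_STATE)
            ]
            series.append(np.array([(t, s) for t, s in obs]))
        est = ProgressiveMarkovModel(n_starts=1).fit(series)
        assert est.states_ == tuple(range(4, 11))
        assert est.converged_ and np.all(est.rates_ > 0)
        assert est.score(series) == pytest.approx(est.log_likelihood_, rel=1e-6)
        curve = est.percentile_curve(50, "any")
        assert isinstance(curve, PercentileCurve)

    def test_unfitted_raises(self):
        with pytest.raises(mk.FitError, match="not fitted"):
            ProgressiveMarkovModel().percentile_curve(50)
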