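import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from labourprogress.markov import BIRTH_STATE
from labourprogress.synthetic import (
    CohortConfig,
    ConfigurationError,
    assign_outcome,
    default_rate_table,
    observe_panel,
    simulate_cohort,
    simulate_trajectory,
    speed_score,
    _outcome_intercept,
    _truncated_count_sampler,
)


class TestTrajectory:
    def test_starts_at_ten_is_single_transition(self, rng):
        path = simulate_trajectory({10: 2.0}, 10, rng)
        assert [s for s, _ in path] == [10, BIRTH_STATE]
        assert path[0][1] == 0.0 and path[1][1] > 0.0

    def test_visits_each_centimetre_once(self, rng):
        rates = {s: 1.0 for s in range(2, 11)}
        path = simulate_trajectory(rates, 3, rng)
        assert [s for s, _ in path] == list(range(3, 11)) + [BIRTH_STATE]
        assert np.all(np.diff([t for _, t in path]) > 0)

    def test_sojourn_mean_matches_rate(self, rng):
        waits = [
            simulate_trajectory({9: 1.0, 10: 1.0}, 9, rng)[1][1] for _ in range(4000)
        ]
        assert np.mean(waits) == pytest.approx(1.0, abs=3 * 1.0 / np.sqrt(4000))

    def test_mean_passage_time_sums_exponential_means(self, rng):
        """All rates 0.5/h from 4 cm: the 4->10 cm time averages ~12 h."""
        rates = {s: 0.5 for s in range(2, 11)}
        times = []
        for _ in range(10_000):
            path = simulate_trajectory(rates, 4, rng)
            times.append(dict((s, t) for s, t in path)[10])
        se = np.std(times) / np.sqrt(len(times))
        assert np.mean(times) == pytest.approx(12.0, abs=3 * se)

    def test_missing_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="state 7"):
            simulate_trajectory({s: 1.0 for s in (5, 6, 8, 9, 10)}, 5, rng)


class TestObservePanel:
    PATH = [(3, 0.0), (4, 1.0), (5, 2.5), (6, 4.0), (7, 5.0), (8, 6.0), (9, 7.0), (10, 8.0), (BIRTH_STATE, 9.0)]

    def test_explicit_schedule_samples_step_function(self, rng):
        exams = observe_panel(self.PATH, [0.0, 4.0, 8.0], rng)
        assert exams == [(0.0, 3), (4.0, 6), (8.0, 10)]

    def test_zero_extra_exams_returns_admission_only(self, rng):
        exams = observe_panel(self.PATH, lambda r: 0, rng)
        assert exams == [(0.0, 3)]

    def test_recorded_dilatation_equals_latent_state(self, rng):
        exams = observe_panel(self.PATH, lambda r: 5, rng)
        for t, d in exams:
            latent = max(s for s, entry in self.PATH if entry <= t and s <= 10)
            assert d == latent
        times = [t for t, _ in exams]
        assert times == sorted(times)

    def test_count_sampler_matches_target_moments(self, rng):
        sampler = _truncated_count_sampler(2.22, 1.02)
        draws = np.array([sampler(rng) for _ in range(20_000)])
        assert np.min(draws) >= 1
        assert np.mean(draws) == pytest.approx(2.22, abs=0.03)
        assert np.std(draws) == pytest.approx(1.02, abs=0.05)


class TestOutcomeModel:
    def test_null_multiplier_gives_baseline_probability(self, rng):
        config = CohortConfig(slow_labour_odds_multiplier=1.0, p_adverse_baseline=0.1)
        draws = [assign_outcome(s, config, rng) for s in rng.normal(size=5000)]
        # independent of the score, the rate is the plain baseline
        assert np.mean(draws) == pytest.approx(0.1, abs=3 * 0.3 / np.sqrt(5000))

    def test_intercept_calibration_restores_marginal(self):
        alpha = _outcome_intercept(0.022, 1.35, 4.0)
        from scipy.special import expit
        from scipy import stats

        grid = (np.arange(4096) + 0.5) / 4096
        f = stats.gamma.ppf(grid, a=4.0, scale=0.25)
        scores = np.array([speed_score(fi, 4.0) for fi in f])
        marginal = np.mean(expit(alpha + np.log(1.35) * scores))
        assert marginal == pytest.approx(0.022, abs=1e-4)

    def test_non_finite_score_rejected(self, rng):
        with pytest.raises(ValueError, match="finite"):
            assign_outcome(np.inf, CohortConfig(), rng)


class TestCohort:
    def test_same_seed_gives_identical_csv_bytes(self):
        frames = []
        for _ in range(2):
            women, exams = simulate_cohort(CohortConfig(n_women=100, seed=42))
            buf_w, buf_e = io.StringIO(), io.StringIO()
            women.to_csv(buf_w, index=False)
            exams.to_csv(buf_e, index=False)
            frames.append((buf_w.getvalue(), buf_e.getvalue()))
        assert frames[0] == frames[1]

    def test_different_seeds_differ(self):
        w1, _ = simulate_cohort(CohortConfig(n_women=50, seed=1))
        w2, _ = simulate_cohort(CohortConfig(n_women=50, seed=2))
        assert not w1.equals(w2)

    def test_invalid_config_lists_offending_fields(self):
        bad = CohortConfig(n_women=0, p_augmentation=1.4, exam_count_sd=-1)
        with pytest.raises(ConfigurationError) as err:
            bad.validate()
        msg = str(err.value)
        assert "n_women" in msg and "p_augmentation" in msg and "exam_count_sd" in msg

    def test_marginals_near_configured_values(self, small_cohort):
        women, exams = small_cohort
        n = len(women)
        for col, p in (
            ("augmentation", 0.351),
            ("caesarean", 0.132),
            ("previous_caesarean", 0.054 * (1 - 0.408)),
        ):
            se = np.sqrt(p * (1 - p) / n)
            assert women[col].mean() == pytest.approx(p, abs=4 * se)
        assert (women.onset == "spontaneous").mean() == pytest.approx(
            0.899, abs=4 * np.sqrt(0.899 * 0.101 / n)
        )
        assert (women.parity == 0).mean() == pytest.approx(
            0.408, abs=4 * np.sqrt(0.408 * 0.592 / n)
        )
        assert (women.presentation == "cephalic").mean() == pytest.approx(
            0.986, abs=4 * np.sqrt(0.986 * 0.014 / n)
        )

    def test_exam_series_valid_and_admission_bounded(self, small_cohort):
        women, exams = small_cohort
        assert set(exams.columns) == {"id", "time_hours", "dilatation_cm"}
        for wid, grp in exams.groupby("id"):
            t = grp["time_hours"].to_numpy()
            d = grp["dilatation_cm"].to_numpy()
            assert np.all(np.diff(t) > 0)
            assert np.all(np.diff(d) >= 0)
            assert t[0] == 0.0 and 1 <= d[0] <= 6
        # exams never extend past the recorded birth time
        merged = exams.merge(women[["id", "birth_time"]], on="id")
        assert (merged.time_hours <= merged.birth_time + 1e-9).all()

    def test_birth_time_always_recorded(self, small_cohort):
        women, _ = small_cohort
        assert women["birth_time"].notna().all()
        assert (women["birth_time"] > 0).all()

    def test_default_rate_table_covers_all_subgroups(self):
        table = default_rate_table()
        assert len(table) == 13  # 12 modelled subgroups + pooled
        for rates in table.values():
            assert set(rates) == set(range(2, 11))
            assert all(r > 0 for r in rates.values())
        # nulliparous groups slower than their multiparous counterparts
        assert table["1N"][5] < table["3N"][5]
        # augmentation marks slower labour within a group
        assert table["3A"][5] < table["3N"][5]

    def test_config_yaml_roundtrip(self, tmp_path):
        config = dataclasses.replace(CohortConfig(), n_women=123, seed=9)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        loaded = CohortConfig.from_yaml(path)
        assert loaded == config
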