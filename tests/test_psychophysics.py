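"""Staircase mechanics, Weibull fitting, and the simulated behavioral experiment."""

import numpy as np
import pandas as pd
import pytest

from normatt.nma import ConfigurationError, ModelParams
from normatt.psychophysics import (
    CRITERION,
    ObserverModel,
    StaircaseConfig,
    fit_psychometric,
    run_staircases,
    simulate_behavioral_experiment,
    staircase_convergence_level,
    weibull_p,
)
from normatt.suppression import si_table_from_thresholds


class TestWeibull:
    def test_guess_floor_at_short_durations(self):
        obs = ObserverModel(alpha=80.0)
        assert weibull_p(1e-6, obs) == pytest.approx(0.5, abs=1e-6)

    def test_ceiling_without_lapses(self):
        obs = ObserverModel(alpha=80.0, lapse=0.0)
        assert weibull_p(1e5, obs) == pytest.approx(1.0, abs=1e-9)

    def test_criterion_level_at_threshold(self):
        # the threshold parameter is defined at the 79% success level
        for beta in (1.0, 3.0, 7.0):
            obs = ObserverModel(alpha=80.0, beta=beta, lapse=0.0)
            assert weibull_p(80.0, obs) == pytest.approx(CRITERION, abs=1e-12)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            weibull_p(0.0, ObserverModel(alpha=80.0))

    @pytest.mark.parametrize("kwargs", [
        {"alpha": -1.0}, {"alpha": 80.0, "beta": 0.0},
        {"alpha": 80.0, "lapse": 0.5}, {"alpha": 80.0, "gamma": 0.6},
    ])
    def test_invalid_observer_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ObserverModel(**kwargs)


class TestStaircase:
    def test_tracks_alternate_and_start_as_configured(self):
        obs = ObserverModel(alpha=80.0)
        trials = run_staircases(obs, seed=0)
        assert len(trials) == 200
        assert trials["track"].tolist()[:4] == [0, 1, 0, 1]
        assert trials.loc[0, "duration_ms"] == 33.0
        assert trials.loc[1, "duration_ms"] == 158.0

    def test_perfect_observer_only_descends(self):
        # an observer at ceiling answers every trial correctly: duration
        # drops by one step after every 3rd trial of a track, never rises
        obs = ObserverModel(alpha=1e-3, beta=3.0, lapse=0.0)
        trials = run_staircases(obs, seed=1)
        assert trials["correct"].all()
        for track in (0, 1):
            d = trials.loc[trials["track"] == track, "duration_ms"].to_numpy()
            assert np.all(np.diff(d) <= 1e-12)
            changes = np.nonzero(np.diff(d) < 0)[0]
            floor_free = changes[d[changes] > 8.3 * 1.27]
            assert np.all(np.diff(floor_free) % 3 == 0)

    def test_easy_observer_descends_to_floor(self):
        obs = ObserverModel(alpha=1e-3, beta=3.0, lapse=0.0)
        cfg = StaircaseConfig()
        trials = run_staircases(obs, cfg, seed=2)
        assert trials["duration_ms"].iloc[-1] == pytest.approx(cfg.floor, rel=0.3)
        assert trials["duration_ms"].min() >= cfg.floor

    def test_durations_respect_bounds(self):
        obs = ObserverModel(alpha=300.0, beta=2.0, lapse=0.05)
        cfg = StaircaseConfig()
        trials = run_staircases(obs, cfg, seed=3)
        assert trials["duration_ms"].between(cfg.floor, cfg.ceiling).all()

    def test_convergence_to_79_percent(self):
        # 1-up/3-down converges at p where p^3 = 0.5, i.e. 79.4% correct
        obs = ObserverModel(alpha=80.0, beta=3.0, lapse=0.0)
        levels = [staircase_convergence_level(obs, n_trials=10_000, burn_in=500, seed=s)
                  for s in range(100)]
        levels = np.array(levels)
        assert np.all(np.abs(levels - 0.5 ** (1 / 3)) < 0.02)

    def test_determinism(self):
        obs = ObserverModel(alpha=60.0)
        a = run_staircases(obs, seed=11)
        b = run_staircases(obs, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            StaircaseConfig(start_durations=(33.0,))
        with pytest.raises(ConfigurationError):
            StaircaseConfig(step_factor=0.9)
        with pytest.raises(ConfigurationError):
            StaircaseConfig(floor=-1.0)


class TestPsychometricFit:
    @staticmethod
    def _trials(alpha=80.0, seed=0, **kw):
        obs = ObserverModel(alpha=alpha, beta=3.0, lapse=0.01)
        return run_staircases(obs, seed=seed, **kw)

    def test_threshold_recovery_across_replicates(self):
        # 200 staircase trials recover the generating 80 ms threshold:
        # within 15% in >= 90% of replicates and with a near-unbiased median
        true_alpha = 80.0
        est = []
        for seed in range(100):
            fitres = fit_psychometric(self._trials(true_alpha, seed=seed))
            est.append(fitres.threshold_ms)
        est = np.array(est)
        within = np.abs(est - true_alpha) / true_alpha < 0.15
        assert within.mean() >= 0.90
        assert 0.95 <= np.median(est) / true_alpha <= 1.05

    def test_duplicated_trials_leave_estimate_unchanged(self):
        trials = self._trials(seed=5)
        doubled = pd.concat([trials, trials], ignore_index=True)
        a = fit_psychometric(trials)
        b = fit_psychometric(doubled)
        assert b.threshold_ms == pytest.approx(a.threshold_ms, rel=1e-4)

    def test_all_correct_data_rejected(self):
        trials = pd.DataFrame({
            "duration_ms": np.tile([10.0, 20.0, 40.0, 80.0], 20),
            "correct": True,
        })
        with pytest.raises(ConfigurationError):
            fit_psychometric(trials)

    def test_too_few_distinct_durations_rejected(self):
        trials = pd.DataFrame({
            "duration_ms": np.tile([10.0, 20.0], 40),
            "correct": np.tile([True, False], 40),
        })
        with pytest.raises(ConfigurationError):
            fit_psychometric(trials)

    def test_step_observer_pins_slope_at_bound(self):
        # step-function observer sampled tightly around its step: perfect
        # just above 50 ms, exactly at chance just below, so the likelihood
        # pushes the slope into its upper bound
        d = np.tile([44.0, 47.0, 49.0, 51.0, 53.0, 56.0], 40)
        correct = np.where(d > 50.0, True, np.arange(d.size) % 2 == 0)
        fitres = fit_psychometric(pd.DataFrame({"duration_ms": d, "correct": correct}))
        assert fitres.slope_at_bound

    def test_interleaved_tracks_agree(self):
        # the 33 ms and 158 ms tracks converge to the same threshold: the
        # per-track estimates are statistically indistinguishable across seeds
        from scipy import stats
        obs = ObserverModel(alpha=70.0, beta=3.0, lapse=0.01)
        diffs = []
        for seed in range(100):
            trials = run_staircases(obs, seed=seed)
            t0 = fit_psychometric(trials[trials["track"] == 0])
            t1 = fit_psychometric(trials[trials["track"] == 1])
            diffs.append(t0.threshold_ms - t1.threshold_ms)
        res = stats.ttest_1samp(diffs, 0.0)
        assert res.pvalue > 0.05


class TestBehavioralSimulation:
    def test_deterministic_given_seed(self, predictor, truth_params):
        cfg = StaircaseConfig(trials_per_track=40)
        a = simulate_behavioral_experiment(truth_params, n_participants=2, seed=9,
                                           predictor=predictor, config=cfg)
        b = simulate_behavioral_experiment(truth_params, n_participants=2, seed=9,
                                           predictor=predictor, config=cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_group_suppression_pattern(self, predictor, truth_params):
        # same-direction SIs positive and larger under wide attention;
        # opposite-direction SIs near zero — the behavioral signature
        table = simulate_behavioral_experiment(truth_params, n_participants=8,
                                               seed=17, predictor=predictor)
        si = si_table_from_thresholds(table)
        means = si.groupby(["attention", "direction"])["si"].mean()
        assert means[("wide", "same")] > means[("narrow", "same")] > 0.0
        assert abs(means[("narrow", "opposite")]) < means[("narrow", "same")]
        assert abs(means[("wide", "opposite")]) < means[("wide", "same")]
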