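"""Simulated behavioral experiment: adaptive staircases and Weibull thresholds.

Motion direction discrimination is a two-alternative task, so a simulated
observer answers correctly with probability

    p(d) = gamma + (1 - gamma - lambda) * (1 - exp(-(d / alpha_w)**beta))

where ``d`` is the stimulus duration (ms), ``gamma = 0.5`` is the guess rate,
``lambda`` a small lapse rate, and ``alpha_w`` is parameterized so that
``p(alpha) = 0.79`` when ``lambda = 0`` — i.e. the observer's nominal
threshold ``alpha`` is the duration supporting 79% correct, the level an
ideal 1-up/3-down staircase converges to (0.5 ** (1/3) = 79.4%).

Stimulus duration is driven by two interleaved 1-up/3-down staircases (one
starting easy, one hard) with multiplicative steps; thresholds are recovered
by maximum-likelihood Weibull fits to the pooled trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp as _exp

import numpy as np
import pandas as pd
from scipy import optimize

from .nma import ConditionPredictor, ConfigurationError, ModelParams

__all__ = [
    "CRITERION",
    "ObserverModel",
    "StaircaseConfig",
    "PsychometricFit",
    "weibull_p",
    "run_staircases",
    "staircase_convergence_level",
    "fit_psychometric",
    "simulate_behavioral_experiment",
]

#: Criterion proportion correct at which duration thresholds are read out.
CRITERION = 0.79

_LAPSE_MAX = 0.06
_BETA_BOUNDS = (0.2, 20.0)


@dataclass(frozen=True)
class ObserverModel:
    """Weibull observer for the two-alternative direction judgment."""

    alpha: float  # duration (ms) at the 79%-correct criterion (lapse-free)
    beta: float = 3.0  # psychometric slope
    gamma: float = 0.5  # guess rate, fixed by the two-alternative design
    lapse: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("alpha and beta must be positive")
        if not (0.0 <= self.lapse <= _LAPSE_MAX):
            raise ConfigurationError(f"lapse must lie in [0, {_LAPSE_MAX}]")
        if self.gamma != 0.5:
            raise ConfigurationError("gamma is fixed at 0.5 for the direction judgment")


@dataclass(frozen=True)
class StaircaseConfig:
    """Two interleaved 1-up/3-down tracks with multiplicative duration steps.

    Defaults: tracks start at 33 ms (hard) and 158 ms (easy), 100 trials per
    track, step factor 1.26 (~2 dB), duration clamped to [8.3, 500] ms (the
    floor is one frame of a 120 Hz display).
    """

    start_durations: tuple[float, float] = (33.0, 158.0)
    trials_per_track: int = 100
    step_factor: float = 1.26
    floor: float = 8.3
    ceiling: float = 500.0

    def __post_init__(self):
        if len(self.start_durations) != 2:
            raise ConfigurationError("exactly two interleaved tracks are required")
        if self.step_factor <= 1.0:
            raise ConfigurationError("step_factor must exceed 1")
        if not (0 < self.floor < self.ceiling):
            raise ConfigurationError("need 0 < floor < ceiling")
        if any(not (self.floor <= s <= self.ceiling) for s in self.start_durations):
            raise ConfigurationError("start durations must lie within [floor, ceiling]")
        if self.trials_per_track < 1:
            raise ConfigurationError("trials_per_track must be >= 1")


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood Weibull fit and the 79%-correct duration threshold."""

    alpha: float
    beta: float
    lapse: float
    threshold_ms: float
    nll: float
    slope_at_bound: bool


def _alpha_w(alpha: float, beta: float) -> float:
    # p(alpha) = 0.79 when lapse = 0  =>  (alpha/alpha_w)**beta = -log(0.42)
    k = -np.log(1.0 - (CRITERION - 0.5) / 0.5)
    return alpha / k ** (1.0 / beta)


def weibull_p(duration, observer: ObserverModel):
    """Probability of a correct response at the given duration(s), ms."""
    d = np.asarray(duration, dtype=float)
    if np.any(d <= 0):
        raise ConfigurationError("duration must be positive")
    aw = _alpha_w(observer.alpha, observer.beta)
    p = observer.gamma + (1.0 - observer.gamma - observer.lapse) * (
        1.0 - np.exp(-((d / aw) ** observer.beta)))
    return p if p.shape else float(p)


def run_staircases(
    observer: ObserverModel,
    config: StaircaseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the two interleaved 1-up/3-down tracks, alternating trial by
    trial.  Within a track the duration is divided by the step factor after 3
    consecutive correct responses and multiplied by it after each error.

    Returns a trial table with columns ``trial, track, duration_ms, correct``.
    """
    config = config if config is not None else StaircaseConfig()
    rng = np.random.default_rng(seed)
    durations = [float(s) for s in config.start_durations]
    run_correct = [0, 0]
    rows = []
    n_total = 2 * config.trials_per_track
    draws = rng.random(n_total)
    # scalar psychometric evaluation inlined for speed (this loop runs for
    # millions of trials in convergence checks)
    aw = _alpha_w(observer.alpha, observer.beta)
    top = 1.0 - observer.gamma - observer.lapse
    g, b = observer.gamma, observer.beta
    for t in range(n_total):
        track = t % 2
        d = durations[track]
        try:
            p = g + top * (1.0 - _exp(-((d / aw) ** b)))
        except OverflowError:  # far above threshold: ceiling performance
            p = g + top
        correct = bool(draws[t] < p)
        rows.append((t, track, d, correct))
        if correct:
            run_correct[track] += 1
            if run_correct[track] == 3:
                durations[track] = max(config.floor, d / config.step_factor)
                run_correct[track] = 0
        else:
            run_correct[track] = 0
            durations[track] = min(config.ceiling, d * config.step_factor)
    return pd.DataFrame(rows, columns=["trial", "track", "duration_ms", "correct"])


def staircase_convergence_level(
    observer: ObserverModel,
    n_trials: int = 10_000,
    burn_in: int = 500,
    config: StaircaseConfig | None = None,
    seed: int = 0,
) -> float:
    """Long-run proportion correct of a single 1-up/3-down track after a
    burn-in, for checking convergence to the theoretical 0.5**(1/3) = 0.794."""
    base = config if config is not None else StaircaseConfig()
    cfg = StaircaseConfig(start_durations=base.start_durations,
                          trials_per_track=(n_trials + burn_in + 1) // 2,
                          step_factor=base.step_factor,
                          floor=base.floor, ceiling=base.ceiling)
    trials = run_staircases(observer, cfg, seed=seed)
    post = trials.iloc[burn_in:]
    return float(post["correct"].mean())


def _nll(theta, durations, correct):
    alpha, beta, lapse = theta
    obs = ObserverModel(alpha=alpha, beta=beta, lapse=lapse)
    p = np.clip(weibull_p(durations, obs), 1e-9, 1.0 - 1e-9)
    return -np.sum(np.where(correct, np.log(p), np.log1p(-p)))


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood Weibull fit to a trial table (gamma fixed at 0.5,
    lapse bounded [0, 0.06]); returns the duration at 79% correct.

    Pools all provided trials into one likelihood.  Raises when the threshold
    is unidentifiable (all responses correct or all incorrect).
    """
    durations = trials["duration_ms"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)
    if durations.size < 4 or np.unique(durations).size < 3:
        raise ConfigurationError("need trials spanning at least 3 distinct durations")
    if correct.all() or (~correct).all():
        raise ConfigurationError("threshold unidentifiable: responses are all "
                                 "correct or all incorrect")
    lo, hi = durations.min(), durations.max()
    bounds = [(lo / 10.0, hi * 10.0), _BETA_BOUNDS, (0.0, _LAPSE_MAX)]
    best = None
    for a0 in (np.median(durations), lo, hi):
        for b0 in (1.0, 3.0, 12.0):
            res = optimize.minimize(
                _nll, x0=np.array([a0, b0, 0.01]),
                args=(durations, correct), method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta, lapse = best.x
    # duration at absolute 79% correct under the fitted lapse
    frac = (CRITERION - 0.5) / (0.5 - lapse)
    if frac >= 1.0:
        raise ConfigurationError("fitted lapse leaves the 79% level unreachable")
    threshold = _alpha_w(alpha, beta) * (-np.log1p(-frac)) ** (1.0 / beta)
    return PsychometricFit(alpha=float(alpha), beta=float(beta), lapse=float(lapse),
                           threshold_ms=float(threshold), nll=float(best.fun),
                           slope_at_bound=bool(np.isclose(beta, _BETA_BOUNDS[1])))


def simulate_behavioral_experiment(
    params: ModelParams,
    n_participants: int = 10,
    seed: int = 0,
    predictor: ConditionPredictor | None = None,
    config: StaircaseConfig | None = None,
    threshold_jitter_sd: float = 0.2,
    observer_beta: float = 3.0,
    observer_lapse: float = 0.01,
) -> pd.DataFrame:
    """End-to-end behavioral simulation: per participant and condition, the
    observer's threshold is the model-predicted duration (T = C / R_peak)
    jittered by a participant-level lognormal factor; staircases are run and
    thresholds re-estimated by Weibull fitting.

    Returns a threshold table with columns ``participant, condition,
    threshold_ms`` ready for suppression-index analysis.
    """
    predictor = predictor if predictor is not None else ConditionPredictor()
    prediction = predictor.predict(params)
    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    stair_seeds = ss.generate_state(n_participants * len(predictor.names)) % (2**31)
    rows = []
    i = 0
    for p in range(n_participants):
        factor = float(jitter_rng.lognormal(mean=0.0, sigma=threshold_jitter_sd)) \
            if threshold_jitter_sd > 0 else 1.0
        for cond in predictor.names:
            obs = ObserverModel(alpha=prediction.threshold_ms[cond] * factor,
                                beta=observer_beta, lapse=observer_lapse)
            trials = run_staircases(obs, config, seed=int(stair_seeds[i]))
            i += 1
            est = fit_psychometric(trials)
            rows.append((f"P{p + 1:02d}", cond, est.threshold_ms))
    return pd.DataFrame(rows, columns=["participant", "condition", "threshold_ms"])
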