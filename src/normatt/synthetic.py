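"""Synthetic fMRI beta tables and behavioral observers.

Generation starts at the beta-weight level the model fitting consumes: per
participant, each condition's beta is the forward-model peak response scaled
by a participant-level lognormal factor plus additive Gaussian noise.  The
defaults emulate the study conditions: 10 participants, five conditions,
noise SD equal to 10% of the center-only response, participant scale
lognormal SD 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nma import ConditionPredictor, ConfigurationError, ModelParams
from .psychophysics import ObserverModel

__all__ = ["GeneratorConfig", "gen_fmri_betas", "gen_observers"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and noise structure of the generator.

    ``noise_sd`` is the additive beta noise expressed as a fraction of the
    ground-truth center-only peak response; ``scale_sd`` is the lognormal SD
    of the per-participant multiplicative gain.
    """

    params: ModelParams = field(default_factory=ModelParams)
    n_participants: int = 10
    scale_sd: float = 0.2
    noise_sd: float = 0.10
    seed: int = 0
    observer_beta_range: tuple[float, float] = (2.0, 4.0)
    observer_lapse_range: tuple[float, float] = (0.0, 0.04)
    threshold_jitter_sd: float = 0.2

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("need at least 2 participants")
        if self.noise_sd < 0 or self.scale_sd < 0 or self.threshold_jitter_sd < 0:
            raise ConfigurationError("noise parameters must be nonnegative")


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def gen_fmri_betas(config: GeneratorConfig | None = None,
                   predictor: ConditionPredictor | None = None) -> pd.DataFrame:
    """Generate a complete beta table (participant, condition, beta).

    beta = participant_scale x R_peak(condition; ground-truth params)
           + N(0, noise_sd x R_peak(center_only)).
    """
    config = config if config is not None else GeneratorConfig()
    predictor = predictor if predictor is not None else ConditionPredictor()
    prediction = predictor.predict(config.params)
    rng = np.random.default_rng(config.seed)
    noise_scale = config.noise_sd * prediction.r_peak["center_only"]
    rows = []
    for pid in _participant_ids(config.n_participants):
        scale = rng.lognormal(0.0, config.scale_sd) if config.scale_sd > 0 else 1.0
        for cond in predictor.names:
            beta = scale * prediction.r_peak[cond]
            if noise_scale > 0:
                beta += rng.normal(0.0, noise_scale)
            rows.append((pid, cond, beta))
    return pd.DataFrame(rows, columns=["participant", "condition", "beta"])


def gen_observers(config: GeneratorConfig | None = None,
                  predictor: ConditionPredictor | None = None) -> pd.DataFrame:
    """Generate per-participant, per-condition Weibull observers whose
    thresholds are the model-predicted durations (T = C / R_peak) jittered by
    a participant-level lognormal factor.

    Returns a table with columns ``participant, condition, observer`` where
    ``observer`` holds :class:`~normatt.psychophysics.ObserverModel` objects,
    plus the numeric ``alpha_ms`` column.
    """
    config = config if config is not None else GeneratorConfig()
    predictor = predictor if predictor is not None else ConditionPredictor()
    prediction = predictor.predict(config.params)
    rng = np.random.default_rng(config.seed)
    b_lo, b_hi = config.observer_beta_range
    l_lo, l_hi = config.observer_lapse_range
    rows = []
    for pid in _participant_ids(config.n_participants):
        factor = rng.lognormal(0.0, config.threshold_jitter_sd) \
            if config.threshold_jitter_sd > 0 else 1.0
        for cond in predictor.names:
            obs = ObserverModel(
                alpha=prediction.threshold_ms[cond] * factor,
                beta=float(rng.uniform(b_lo, b_hi)),
                lapse=float(rng.uniform(l_lo, l_hi)),
            )
            rows.append((pid, cond, obs, obs.alpha))
    return pd.DataFrame(rows, columns=["participant", "condition", "observer", "alpha_ms"])
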