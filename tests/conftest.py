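import numpy as np
import pandas as pd
import pytest

from normatt.nma import ConditionPredictor, ModelParams, build_grid


@pytest.fixture(scope="session")
def predictor():
    """Default-grid forward model, shared across tests (stimulus fields cached)."""
    return ConditionPredictor()


@pytest.fixture(scope="session")
def truth_params():
    """Ground-truth parameter set (the group-level optimized widths)."""
    return ModelParams()


@pytest.fixture(scope="session")
def noiseless_vector(predictor, truth_params):
    """Normalized condition responses generated by the model itself."""
    return pd.Series(predictor.predict(truth_params).normalized)


@pytest.fixture(scope="session")
def small_grid():
    """Tiny lattice on which brute-force nested-sum oracles are tractable."""
    return build_grid(n_space=9, space_extent=4.0, n_direction=8)
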