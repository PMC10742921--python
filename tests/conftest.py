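"""Shared synthetic fixtures.

Everything is generated programmatically from fixed seeds; no data files.
Session scope keeps the heavier calibrations to a single run.
"""

import numpy as np
import pytest

import raschmf as rm


@pytest.fixture(scope="session")
def rank4_complete():
    """Noise-free rank-4 complete matrix with known truth."""
    spec = rm.SimulationSpec(n_persons=150, n_items=80, true_d=4,
                             noise_base=0.0, missing_fraction=0.0)
    return rm.simulate_dataset(spec, seed=7)


@pytest.fixture(scope="session")
def rank6_blocked():
    """Noise-free rank-6 matrix with 25% blocked missingness."""
    spec = rm.SimulationSpec(n_persons=200, n_items=100, true_d=6,
                             noise_base=0.0, missing_fraction=0.25,
                             missing_pattern="blocked")
    return rm.simulate_dataset(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_random():
    """Heteroscedastic noisy rank-4 matrix with random missingness."""
    spec = rm.SimulationSpec(n_persons=200, n_items=80, true_d=4,
                             noise_base=0.5, row_noise_spread=0.5,
                             col_noise_spread=0.5, missing_fraction=0.15,
                             missing_pattern="random")
    return rm.simulate_dataset(spec, seed=5)


@pytest.fixture(scope="session")
def instrument():
    """Mixed-metric screening instrument with ages and construct ratings."""
    spec = rm.SimulationSpec(n_persons=250, n_items=80, true_d=5)
    dm, truth, ages, ratings = rm.simulate_instrument(spec, seed=7)
    return dm, truth, ages, ratings


@pytest.fixture(scope="session")
def fitted_model(instrument):
    """Calibrated RiskScaleModel on the instrument fixture."""
    dm, truth, ages, ratings = instrument
    return rm.RiskScaleModel(d_residual=4, seed=11).fit(dm, ages, ratings)
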