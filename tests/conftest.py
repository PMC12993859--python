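"""Shared fixtures: small, seeded synthetic runs reused across test modules."""

import numpy as np
import pytest

from nutrimon.rf import RFConfig
from nutrimon.synthetic import (
    ExperimentDesign,
    GrowthModel,
    render_experiment,
    simulate_experiment,
)
from nutrimon.vi import build_feature_table, default_registry


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale layout: 12 plants/tank, one destructive sample per tank-day."""
    return ExperimentDesign(plants_per_tank=12, samples_per_tank_per_day=1, seed=7)


@pytest.fixture(scope="session")
def quiet_model():
    """Low-noise generating model with deterministic reflectance rendering."""
    return GrowthModel(pixel_noise_sd=0.0, tank_sd=0.0, residual_sd=0.02,
                      conc_residual_sd=0.005)


@pytest.fixture(scope="session")
def small_experiment(small_design, quiet_model):
    states, ground_truth = simulate_experiment(small_design, quiet_model)
    return states, ground_truth


@pytest.fixture(scope="session")
def named_registry():
    return default_registry(named_only=True)


@pytest.fixture(scope="session")
def feature_tables(small_experiment, quiet_model, named_registry):
    """(single-image, daily-average) VI feature tables from rendered captures."""
    states, _ = small_experiment
    captures = list(render_experiment(states, quiet_model, size=(64, 96),
                                      captures_per_night=2, seed=7))
    single = build_feature_table(captures, named_registry, mode="single-image")
    daily = build_feature_table(captures, named_registry, mode="daily-average")
    return single, daily


@pytest.fixture(scope="session")
def small_rf_config():
    return RFConfig(n_estimators=60, max_depth=12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
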