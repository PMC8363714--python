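"""Shared fixtures: a small end-to-end pipeline reused across test modules.

Scale note: the shared grid uses N=300 populations over 3 kb for 300
generations -- large enough for every class signature to be expressed,
small enough that the whole session's simulations take seconds.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonesel.benchmark import simulate_class_grid
from clonesel.classifier import Hyperparams, build_training_corpus, train_ensemble
from clonesel.features import FeatureConfig
from clonesel.fixtures import FixtureConfig, synth_cohort, synth_panel
from clonesel.params import SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: driver length share of the default synthetic panel; used as the
#: simulator's driver-territory fraction so that simulated training data
#: and panel-mapped cohort data agree on the driver-count feature.
def _panel_driver_share() -> float:
    cfg = FixtureConfig(seed=1234)
    panel = synth_panel(cfg, np.random.default_rng(cfg.seed))
    return float(
        panel.loc[panel["driver"], "length_bp"].sum() / panel["length_bp"].sum()
    )


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    return SimConfig(
        N=300, L=3000, generations=300, driver_frac=_panel_driver_share()
    )


@pytest.fixture(scope="session")
def tiny_feature_config(tiny_sim_config) -> FeatureConfig:
    return FeatureConfig.from_sim_config(tiny_sim_config)


@pytest.fixture(scope="session")
def small_grid(tiny_sim_config):
    """(X, y, Y) for 150 simulations per class at the tiny scale."""
    return simulate_class_grid(150, tiny_sim_config, seed=421)


@pytest.fixture(scope="session")
def small_corpus(small_grid):
    X, y, Y = small_grid
    return build_training_corpus(X, y, Y, seed=17)


@pytest.fixture(scope="session")
def small_hyper() -> Hyperparams:
    return Hyperparams.desk_scale(
        hidden_units=64, ensemble_size=2, subsample_size=8000, seed=5
    )


@pytest.fixture(scope="session")
def small_model(small_corpus, small_hyper):
    return train_ensemble(small_corpus, small_hyper)


@pytest.fixture(scope="session")
def fixture_cohort(tiny_sim_config):
    """40-subject balanced synthetic cohort matching the tiny sim scale."""
    cfg = FixtureConfig(
        n_per_group=5, sim_config=tiny_sim_config, seed=1234
    )
    return cfg, synth_cohort(cfg)
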