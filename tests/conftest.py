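"""Shared fixtures: a miniature one-region world kept small enough that the
whole unit suite runs in a few minutes, plus a fitted model reused by the
prediction/partial-dependence tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sdmtransfer import brt
from sdmtransfer.pipeline import RunConfig, build_population_dataset
from sdmtransfer.synthetic import (RegionSpec, TruthParams, generate_env,
                                   simulate_tracks, true_suitability)

warnings.filterwarnings("ignore", message="selected nt hit max_trees")


@pytest.fixture(scope="session")
def truth():
    return TruthParams()


@pytest.fixture(scope="session")
def mini_region():
    # pacific-style windows on a small extent: cheap but fully featured
    return RegionSpec("mini", 160.0, -49.0, 150.0, 170.0, -55.0, -43.0,
                      n_birds=3,
                      windows={"depth": (-5500, -3000), "t050": (4, 16),
                               "mld": (20, 85), "curr": (0.5, 0.9),
                               "eke": (700, 1500), "chl": (0.05, 0.5)})


@pytest.fixture(scope="session")
def mini_env(mini_region):
    return generate_env(mini_region, seed=123)


@pytest.fixture(scope="session")
def mini_truth_maps(mini_env, truth, mini_region):
    return {m: true_suitability(mini_env, truth, m) for m in mini_region.months}


@pytest.fixture(scope="session")
def mini_tracks(mini_region, mini_truth_maps):
    return simulate_tracks(mini_region, mini_truth_maps, seed=7)


@pytest.fixture(scope="session")
def light_config():
    cfg = RunConfig(seed=0)
    cfg.brt_config = brt.BRTConfig(tree_complexity=2, learning_rate=0.1,
                                   cv_folds=3, max_trees=100, tree_step=25,
                                   seed=0)
    return cfg


@pytest.fixture(scope="session")
def mini_dataset(mini_tracks, mini_env, light_config):
    return build_population_dataset(mini_tracks, mini_env, "mini", light_config)


@pytest.fixture(scope="session")
def mini_model(mini_dataset, light_config):
    return brt.fit_brt(mini_dataset.train, light_config.brt_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
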