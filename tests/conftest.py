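"""Shared fixtures: tiny synthetic worlds reused across the suite.

Session-scoped fixtures hold the expensive artifacts (a trained tiny policy,
the full reference benchmark) so the suite builds each exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pepscreen.agent import PolicyParams, train_policy
from pepscreen.bandit import HotspotSet
from pepscreen.chemspace import DescriptorEmbedding, build_board, fit_projector
from pepscreen.environment import EnvConfig
from pepscreen.oracle import CachedOracle, synthetic_oracle
from pepscreen.screening import PolicyBundle
from pepscreen.synthetic import (
    GroundTruthLandscape,
    SyntheticLibrarySpec,
    make_library,
    make_scaffold_dataset,
)

#: the packaged reference seed for derived expectations
REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def landscape():
    return GroundTruthLandscape.default(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def small_library():
    lib, truth, land = make_library(
        SyntheticLibrarySpec(size=2000, active_fraction=0.05, seed=REFERENCE_SEED)
    )
    return lib, truth, land


@pytest.fixture(scope="session")
def scaffold_dataset():
    ds, land = make_scaffold_dataset(n=210, noise_sd=5.0, seed=REFERENCE_SEED)
    return ds, land


@pytest.fixture(scope="session")
def small_world(small_library):
    """Board + projector + oracle for the 2000-peptide library."""
    lib, truth, land = small_library
    provider = DescriptorEmbedding()
    projector = fit_projector(provider.embed(lib))
    board = build_board(lib, provider, projector, freeze_extremes=True)
    return board, projector, provider, land


@pytest.fixture(scope="session")
def trained_tiny(small_world):
    """A briefly trained policy + bundle on the small board."""
    board, projector, provider, land = small_world
    oracle = synthetic_oracle(land)
    hotspots = HotspotSet()
    env_config = EnvConfig(max_steps=200)
    params = PolicyParams(iterations=6, steps_per_iteration=1000, seed=REFERENCE_SEED)
    report = train_policy(board, CachedOracle(oracle), hotspots, env_config, params)
    bundle = PolicyBundle.from_training(
        report.policy, params, env_config, projector, hotspots
    )
    return report, bundle, oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(REFERENCE_SEED)
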