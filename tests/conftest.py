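"""Shared fixtures.

The expensive full-scale simulations are session-scoped and shared across
the acceptance tests; unit tests build tiny colonies on the fly.
"""

from __future__ import annotations

import numpy as np
import pytest

from biofilmsig import experiments, runio
from biofilmsig.growth import initialize_biofilm
from biofilmsig.params import GrowthPolicy, SimulationConfig


def tiny_state(n_ring: int = 1, seed: int = 0, **param_overrides):
    """A small colony (7 cells for n_ring=1) with dynamics state initialized."""
    cfg = SimulationConfig()
    cfg.growth = GrowthPolicy(nutrient_free_radius=n_ring, population_cap=10_000)
    for k, v in param_overrides.items():
        setattr(cfg.params, k, v)
    rng = np.random.default_rng(seed)
    state = initialize_biofilm(cfg, rng)
    return state, cfg, rng


@pytest.fixture(scope="session")
def default_run():
    """Full-scale default control run, long enough for ~30 post-growth
    oscillations, with per-cell ThT/signaling history recorded."""
    cfg = experiments.default_config(n_ticks=4200)
    return runio.run(cfg, seed=11)


@pytest.fixture(scope="session")
def nosig_run():
    """Full-scale run with potassium release disabled."""
    return experiments.no_signaling_run(seed=13, n_ticks=3400)


@pytest.fixture(scope="session")
def lowthresh_run():
    """Threshold bounds [-0.4, 2.5]: the reduced-ceiling regime."""
    from biofilmsig.params import ThresholdDistribution

    cfg = experiments.default_config(n_ticks=3400, record_cells_from=None)
    cfg.thresholds = ThresholdDistribution(lower=-0.4, upper=2.5)
    return runio.run(cfg, seed=17)


@pytest.fixture(scope="session")
def highthresh_run():
    """Threshold bounds [0.3, 2.9]: the raised-floor regime."""
    from biofilmsig.params import ThresholdDistribution

    cfg = experiments.default_config(n_ticks=3400, record_cells_from=None)
    cfg.thresholds = ThresholdDistribution(lower=0.3, upper=2.9)
    return runio.run(cfg, seed=19)


@pytest.fixture(scope="session")
def lowglu_run():
    """Reduced basal glutamate (20 mM) with growth capped at radius ~90."""
    from biofilmsig import environment

    cfg = experiments.default_config(n_ticks=2500, record_cells_from=None)
    env, radius_cap = environment.preset_low_glutamate()
    cfg.g_m = env.g_m
    cfg.growth.radius_cap = radius_cap
    return runio.run(cfg, seed=23, env=env)


@pytest.fixture(scope="session")
def sync_indices():
    """Asynchrony indices for donor distances 2000 and 4000 um (10 replicates)."""
    return experiments.asynchrony_sweep([2000.0, 4000.0], replicates=10, seed=29)


@pytest.fixture(scope="session")
def small_run():
    """A small, quick run (population cap 6000) for I/O and plumbing tests."""
    cfg = experiments.default_config(n_ticks=250, record_cells_from=None)
    cfg.growth = GrowthPolicy(nutrient_free_radius=20, population_cap=6000)
    return runio.run(cfg, seed=5)
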