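"""Shared fixtures: the simulation ensemble used by engine and acceptance tests.

The ensemble mirrors the study conditions (full parameter table, 30 um
periodic box, 1 Hz snapshots, 100 s burn-in) at run lengths short enough
for a desk-scale test session: 400 s per run, two seeds per reaction
rate.  Full fields are kept only for the slowest and fastest runs, which
feed the kymograph checks.
"""

import numpy as np
import pytest

from amoeboid.engine import SimulationConfig, run_simulation
from amoeboid.polarity import BiochemParams

ENSEMBLE_KA = (2.0, 3.0, 4.0, 5.0)
ENSEMBLE_SEEDS = (1, 2)
RUN_DURATION = 400.0
BURN_IN = 100.0


@pytest.fixture(scope="session")
def model_runs():
    """Dict of SnapshotSeries keyed 'ka{k}_s{seed}' for the run ensemble."""
    runs = {}
    for ka in ENSEMBLE_KA:
        for seed in ENSEMBLE_SEEDS:
            store = ka in (2.0, 5.0) and seed == 1
            config = SimulationConfig(
                duration=RUN_DURATION,
                burn_in=BURN_IN,
                seed=seed,
                store_fields=store,
                biochem=BiochemParams(k_a=ka),
            )
            runs[f"ka{ka:.0f}_s{seed}"] = run_simulation(config)
    return runs


@pytest.fixture(scope="session")
def prw_trajectories():
    """Persistent-random-walk control trajectories with known parameters."""
    from amoeboid.motility import prw_generator

    rng = np.random.default_rng(123)
    return [prw_generator(0.15, 26.5, 4000.0, seed=rng) for _ in range(4)]
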