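"""Shared fixtures: small stimulus simulations and synthetic populations.

Everything is generated at test time from fixed seeds; the expensive
objects (trajectories, volume series, pixel precomputations) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import prfdecode as p


@pytest.fixture(scope="session")
def spec() -> p.StimulusSpec:
    return p.StimulusSpec()


@pytest.fixture(scope="session")
def short_schedule() -> p.RunSchedule:
    """One 240-s block per run, no rest periods: 120 volumes/run."""
    return p.RunSchedule(
        initial_rest_s=0.0,
        block_duration_s=240.0,
        n_blocks=1,
        inter_block_rest_s=0.0,
        final_rest_s=0.0,
    )


@pytest.fixture(scope="session")
def volumes3(short_schedule) -> p.VolumeSeries:
    """Three short runs, 360 stimulus volumes."""
    cfg = p.TrajectoryConfig(seed=2)
    tr = p.simulate_trajectory(cfg, 3 * 240 * 60)
    return p.frames_to_volumes(tr, short_schedule, 3)


@pytest.fixture(scope="session")
def train_volumes(volumes3) -> p.VolumeSeries:
    return volumes3.subset(volumes3.run_ids != 0)


def uniform_population(
    n: int, sigma: float, noise: float, seed: int, extent: float = 3.0
) -> p.VoxelPopulation:
    """Voxel population with uniformly scattered RF centers."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-extent, extent, size=(n, 2))
    return p.VoxelPopulation(
        area="uniform",
        C0=np.zeros(n),
        C1=np.ones(n),
        mu=mu,
        sigma=np.full(n, sigma),
        sigma_noise=np.full(n, noise),
    )


@pytest.fixture(scope="session")
def clean_series(volumes3, spec):
    """Low-noise 30-voxel uniform population on the 3-run stimulus."""
    pop = uniform_population(30, 1.0, 0.05, seed=9)
    return p.simulate_responses(pop, volumes3, spec, seed=10)
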