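"""Shared fixtures.

The heavy two-state and Brownian trajectories reproduce the study conditions
(mean dwell times 1 ns, frame spacing 0.01 ns, 100 ns of dynamics) and are
expensive, so they are generated once per session and shared between the
module tests and the acceptance checks.  All seeds are fixed literals.
"""

from __future__ import annotations

import numpy as np
import pytest

import sdpdiff as s
from sdpdiff.synthetic import TwoStateParams, gen_intermittent_trajectory

TWO_STATE_SEED = 101
BROWNIAN_SEED = 202


@pytest.fixture(scope="session")
def two_state():
    """Balanced stop-and-go fixture: tau_w* = tau_m* = 1 ns, D_moving* = 1."""
    params = TwoStateParams(
        tau_w=1.0, tau_m=1.0, d_moving=1.0, jitter_amp=0.02,
        n_molecules=200, duration=100.0, dt=0.01,
        box=s.Box.cubic(5.0), seed=TWO_STATE_SEED,
    )
    traj, truth = gen_intermittent_trajectory(params)
    return s.unwrap(traj), truth


@pytest.fixture(scope="session")
def two_state_seg(two_state):
    traj, _ = two_state
    return s.segment(traj)


@pytest.fixture(scope="session")
def two_state_msd(two_state):
    traj, _ = two_state
    return s.compute_msd(traj, max_lag_fraction=0.1)


@pytest.fixture(scope="session")
def brownian():
    """Pure Brownian fixture: no waiting state, D* = 1 nm^2/ns, 500 walkers."""
    params = TwoStateParams(
        tau_w=0.0, tau_m=1.0, d_moving=1.0, jitter_amp=0.02,
        n_molecules=500, duration=100.0, dt=0.1,
        box=s.Box.cubic(5.0), seed=BROWNIAN_SEED,
    )
    traj, truth = gen_intermittent_trajectory(params)
    return s.unwrap(traj), truth


@pytest.fixture(scope="session")
def brownian_msd(brownian):
    traj, _ = brownian
    return s.compute_msd(traj, max_lag_fraction=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
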