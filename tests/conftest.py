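"""Shared fixtures: small synthetic worlds and trajectories.

Everything is generated in-process with fixed seeds; session scope keeps
the expensive SASA/trajectory work to one pass.
"""

import numpy as np
import pytest
from hypothesis import settings

from nanosar.synthetic import KineticParams, build_world, simulate_trajectory

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def world():
    return build_world(seed=11)


@pytest.fixture(scope="session")
def two_state_traj(world):
    """Symmetric two-state binding run: occupancy 1/2, mean dwell 25 frames."""
    kin = KineticParams.two_state(
        k_on=0.04, k_off=0.04, dt=1.0, n_frames=2000, seed=23
    )
    bundle, truth = simulate_trajectory(world, kin)
    return bundle, truth, kin


@pytest.fixture(scope="session")
def three_state_traj(world):
    """free / stack_dna / stack_swcnt kinetics for mode classification."""
    kin = KineticParams(
        states=("free", "stack_dna", "stack_swcnt"),
        rates={
            ("free", "stack_dna"): 0.02,
            ("free", "stack_swcnt"): 0.02,
            ("stack_dna", "free"): 0.04,
            ("stack_swcnt", "free"): 0.04,
        },
        dt=1.0,
        n_frames=400,
        seed=5,
    )
    bundle, truth = simulate_trajectory(world, kin)
    return bundle, truth, kin


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
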