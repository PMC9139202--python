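"""Shared fixtures.

The heavier flow solutions are session-scoped so unit tests, property
tests and the acceptance suite share one solve each.
"""

import numpy as np
import pytest

from aneuchip import (
    AneurysmParams,
    SolverConfig,
    make_sidewall_aneurysm,
    make_straight_vessel,
    solve_steady,
)

D = 4.0e-3  # reference supply-vessel diameter, meters


@pytest.fixture(scope="session")
def channel_mask_32():
    """Straight 2-D channel, 32 cells across the diameter, walls aligned
    to grid faces, 4 solid padding layers."""
    params = AneurysmParams(vessel_length=2 * D)
    return make_straight_vessel(params, D / 32, wall_offset=4 * (D / 32))


@pytest.fixture(scope="session")
def poiseuille_32(channel_mask_32):
    """Steady channel flow at the reference Reynolds number."""
    cfg = SolverConfig(reynolds=250.0, steady_tol=1e-7)
    return solve_steady(channel_mask_32, cfg)


@pytest.fixture(scope="session")
def aneurysm_mask():
    """2-D sidewall aneurysm on a 256 x 128 grid (64 cells per diameter):
    4 mm vessel, 1.6 mm sac radius, 1.28 mm neck."""
    params = AneurysmParams()
    return make_sidewall_aneurysm(params, D / 64, wall_offset=0.15 * D,
                                  domain_height=2 * D)


@pytest.fixture(scope="session")
def aneurysm_solution(aneurysm_mask):
    """Steady flow through the sidewall aneurysm at Re = 250."""
    cfg = SolverConfig(reynolds=250.0, steady_tol=1e-5, max_steps=40_000)
    return solve_steady(aneurysm_mask, cfg)


@pytest.fixture(scope="session")
def channel_triple():
    """Nested channel solutions at 16/32/64 cells across for grid
    convergence, walls face-aligned at every level."""
    params = AneurysmParams(vessel_length=2 * D)
    sols = []
    for n in (16, 32, 64):
        mask = make_straight_vessel(params, D / n, wall_offset=0.375 * D)
        cfg = SolverConfig(reynolds=50.0, steady_tol=1e-7)
        sols.append(solve_steady(mask, cfg))
    return tuple(sols)


@pytest.fixture(scope="session")
def eta_sweep():
    """Steady channel solves over a penalization-parameter decade sweep."""
    params = AneurysmParams(vessel_length=2 * D)
    mask = make_straight_vessel(params, D / 32, wall_offset=4 * (D / 32))
    out = {}
    for eta in (1e-4, 1e-6, 1e-8):
        cfg = SolverConfig(reynolds=50.0, steady_tol=1e-8, penalization_eta=eta)
        out[eta] = solve_steady(mask, cfg)
    return out
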