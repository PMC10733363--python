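"""Shared fixtures: reference trajectories and one full case-1 training run."""

from __future__ import annotations

import numpy as np
import pytest

from fracbc import RunConfig, TimeGrid, case_parameters, rhs, run_case, solve_caputo


@pytest.fixture(scope="session")
def case1_trajectory():
    """Case-1 reference trajectory on the default grid (101 nodes on [0, 1])."""
    params, order, y0 = case_parameters(1)
    grid = TimeGrid(t0=0.0, h=0.01, n_steps=100)
    return solve_caputo(lambda y: rhs(y, params), np.asarray(y0), order.alpha, grid)


@pytest.fixture(scope="session")
def case1_run():
    """One end-to-end case-1 run with 10 restarts (shared across tests)."""
    return run_case(RunConfig(case_id=1, seed=101, n_restarts=10))
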