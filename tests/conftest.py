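"""Shared fixtures: small grids and a quick fitted model reused across tests."""

import warnings

import numpy as np
import pytest
from shapely.geometry import box

import gridscr
from gridscr.geometry import build_grid
from gridscr.simulate import (
    SimulationConfig,
    simulate_encounters,
    simulate_population,
)


@pytest.fixture(scope="session")
def rect_grid():
    """8 km x 10 km rectangle of 2-km cells (4 x 5 = 20 active)."""
    return build_grid(box(0.0, 0.0, 8.0, 10.0), cell_size=2.0)


@pytest.fixture(scope="session")
def atoll_grid():
    from gridscr.simulate import atoll_ring_grid

    return atoll_ring_grid()


def make_recovery_dataset(seed, grid=None, N_true=300, K=8, lambda0=0.2,
                          sigma=1.0, beta_effort=0.5):
    """One simulated study under the standard recovery conditions:
    a 10x10 grid of 2-km cells unless a grid is given, heterogeneous effort
    with unsampled cells."""
    if grid is None:
        grid = build_grid(box(0.0, 0.0, 20.0, 20.0), cell_size=2.0)
    rng = np.random.default_rng(seed)
    J = grid.n_cells
    effort = np.zeros((J, K))
    n_fished = int(0.6 * J)
    for k in range(K):
        cells = rng.choice(J, size=n_fished, replace=False)
        effort[cells, k] = rng.integers(1, 4, size=n_fished)
    params = gridscr.SCRParams(
        log_lambda0=np.log(lambda0), beta_effort=beta_effort, log_sigma0=np.log(sigma)
    )
    cfg = SimulationConfig(grid=grid, N_true=N_true, effort=effort, params=params,
                           seed=seed)
    pop = simulate_population(cfg, rng)
    data, truth = simulate_encounters(pop, cfg, rng)
    return grid, cfg, pop, data, truth


@pytest.fixture(scope="session")
def small_fit():
    """A quick but real MCMC fit on a small simulated study, with densely
    stored activity centers, reused by estimator and diagnostics tests."""
    grid = build_grid(box(0.0, 0.0, 12.0, 12.0), cell_size=2.0)
    grid, cfg, pop, data, truth = make_recovery_dataset(
        42, grid=grid, N_true=120, K=5
    )
    model = gridscr.SCRModel(data, grid, effects=("effort",), sex_sigma=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            gridscr.MCMCConfig(
                n_iter=2500, n_burn=500, n_chains=3, M=400, seed=5, s_thin=4
            )
        )
    return {"grid": grid, "cfg": cfg, "pop": pop, "data": data, "truth": truth,
            "results": res}
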