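"""Model object tying encounter data, grid and sampler together.

Follows the familiar two-object pattern: build an :class:`SCRModel` from an
:class:`~gridscr.data.EncounterData` and a :class:`~gridscr.geometry.StudyGrid`,
call :meth:`SCRModel.fit` to run the MCMC, and work with the returned
:class:`~gridscr.results.SCRResults`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import EncounterData
from .geometry import StudyGrid
from .likelihood import standardize_covariates
from .sampler import MCMCConfig, Priors, run_chains

__all__ = ["SCRModel", "fit_per_occasion"]


class SCRModel:
    """Grid-cell spatial capture-recapture model with data augmentation.

    Parameters
    ----------
    data
        Binary encounter histories, effort and individual covariates.
    grid
        The sampling grid / state space S.
    effects
        Covariates entering the log-hazard linear predictor, any subset of
        ``("effort", "sex", "size")``.
    sex_sigma
        Whether the range parameter sigma carries a log-linear male offset.
    priors
        Prior hyperparameters; defaults are uninformative.
    """

    def __init__(
        self,
        data: EncounterData,
        grid: StudyGrid,
        effects=("effort", "sex", "size"),
        sex_sigma: bool = True,
        priors: Priors | None = None,
    ):
        data.validate_against_grid(grid)
        self.data = data
        self.grid = grid
        self.effects = tuple(effects)
        self.sex_sigma = bool(sex_sigma)
        self.priors = priors or Priors()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.scaling = standardize_covariates(data.effort, data.size)

    @classmethod
    def from_csv(
        cls,
        captures_path,
        effort_path,
        grid_path,
        ref_latlon=None,
        **kwargs,
    ) -> "SCRModel":
        """Build the model straight from capture/effort/grid CSV files."""
        from .io import read_captures, read_effort
        from .geometry import StudyGrid

        grid = StudyGrid.from_csv(grid_path)
        if ref_latlon is not None:
            object.__setattr__(grid, "ref_latlon", tuple(ref_latlon))
        effort, dates = read_effort(effort_path, grid)
        data = read_captures(captures_path, grid, effort, occasion_dates=dates)
        return cls(data, grid, **kwargs)

    def fit(
        self,
        config: MCMCConfig | None = None,
        *,
        n_iter: int | None = None,
        n_burn: int | None = None,
        n_chains: int | None = None,
        M: int | None = None,
        seed: int | None = None,
        thin: int | None = None,
        fixed_params: dict | None = None,
    ):
        """Run the MCMC and return an :class:`~gridscr.results.SCRResults`.

        Keyword overrides are applied on top of ``config`` (or the defaults:
        3 chains of 12,000 iterations with the first 2,000 discarded as
        burn-in).
        """
        from .results import SCRResults

        cfg = config or MCMCConfig()
        overrides = dict(
            n_iter=n_iter, n_burn=n_burn, n_chains=n_chains, M=M, seed=seed, thin=thin
        )
        changed = {k: v for k, v in overrides.items() if v is not None}
        if changed:
            from dataclasses import replace

            cfg = replace(cfg, **changed)
        post = run_chains(
            self.data,
            self.grid,
            cfg,
            self.priors,
            effects=self.effects,
            sex_sigma=self.sex_sigma,
            scaling=self.scaling,
            fixed_params=fixed_params,
        )
        return SCRResults(self, post)


def fit_per_occasion(
    data: EncounterData,
    grid: StudyGrid,
    cells=None,
    occasions=None,
    config: MCMCConfig | None = None,
    effects=("effort",),
    sex_sigma: bool = False,
    M_factor: int = 6,
    seed: int = 0,
) -> list:
    """Independent closed-population fits, one per occasion.

    Used for the temporal-stability analysis on a consistently sampled cell
    subset: each occasion is fitted as its own closed population (shared prior
    specification, no shared parameters), and the per-occasion N draws feed
    :func:`gridscr.estimates.trend`.
    """
    from .results import SCRResults  # noqa: F401

    occasions = (
        list(range(data.n_occasions)) if occasions is None else list(occasions)
    )
    results = []
    for k in occasions:
        sub = data.subset(cells=cells, occasions=[k])
        subgrid = grid if cells is None else _subgrid(grid, cells)
        if sub.n_individuals == 0:
            raise ValueError(f"no encounters in occasion {k} on the chosen subset")
        cfg = config or MCMCConfig(n_iter=4000, n_burn=1000)
        from dataclasses import replace

        cfg = replace(
            cfg,
            M=max(M_factor * sub.n_individuals, sub.n_individuals + 20),
            seed=seed + 1000 * (k + 1),
        )
        model = SCRModel(sub, subgrid, effects=effects, sex_sigma=sex_sigma)
        results.append(model.fit(cfg))
    return results


def _subgrid(grid: StudyGrid, cells) -> StudyGrid:
    from .geometry import build_grid

    centers = grid.cell_centers[np.asarray(cells)]
    return build_grid(centers=centers, cell_size=grid.cell_size)
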