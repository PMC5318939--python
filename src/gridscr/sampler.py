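"""Chain management for the Metropolis-within-Gibbs SCR sampler.

The sampler alternates exact Gibbs draws (inclusion indicators, latent sex,
psi, psi_sex) with random-walk Metropolis steps (activity centers, latent
sizes, hazard and range parameters).  Proposal scales adapt toward a 0.3
acceptance rate during burn-in only, so the post-burn-in kernel is a fixed,
valid MCMC kernel.  Chains are seeded as ``seed + chain_index`` and are
bit-reproducible.

Default priors (the field study reports only that priors were uninformative;
see docs/methods.md):

* log lambda0 ~ Normal(0, 10^2)
* sigma0 ~ Uniform(0.05, 30) km
* each beta ~ Normal(0, 10^2)
* psi, psi_sex ~ Uniform(0, 1) (conjugate Beta(1, 1) Gibbs updates)
* latent standardized size ~ Normal(0, 1) truncated to the observed range
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _mcmc
from .data import EncounterData
from .geometry import StudyGrid
from .likelihood import CovariateScaling, SCRParams, standardize_covariates

__all__ = [
    "MCMCConfig",
    "Priors",
    "PosteriorSamples",
    "run_chains",
    "gelman_rubin",
    "effective_sample_size",
]

PARAM_NAMES = [
    "log_lambda0",
    "beta_effort",
    "beta_sex",
    "beta_size",
    "log_sigma0",
    "beta_sigma_sex",
    "psi",
    "psi_sex",
]

PROPOSAL_NAMES = [
    "activity_center",
    "log_lambda0",
    "beta_effort",
    "beta_sex",
    "beta_size",
    "log_sigma0",
    "beta_sigma_sex",
    "latent_size",
]


@dataclass
class Priors:
    """Hyperparameters of the (uninformative) priors."""

    mu_log_lambda0: float = 0.0
    sd_log_lambda0: float = 10.0
    sd_beta: float = 10.0
    sigma_range: tuple[float, float] = (0.05, 30.0)


@dataclass
class MCMCConfig:
    """Sampler run configuration.

    ``M`` is the augmented population size (default 8x the number observed,
    comfortably above the study's abundance-to-captures ratio); ``s_thin``
    controls how often (in kept draws) activity centers are stored, to bound
    memory.
    """

    n_iter: int = 12000
    n_burn: int = 2000
    n_chains: int = 3
    M: int | None = None
    thin: int = 1
    s_thin: int = 10
    seed: int = 0
    adapt_every: int = 50
    step_s: float = 0.5
    step_param: float = 0.1
    step_size_latent: float = 0.5

    def __post_init__(self):
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_chains < 2:
            warnings.warn(
                "convergence diagnostics (R-hat) require at least 2 chains",
                stacklevel=2,
            )
        if self.thin < 1 or self.s_thin < 1:
            raise ValueError("thinning intervals must be >= 1")


@dataclass
class PosteriorSamples:
    """Posterior draws from all chains plus sampler diagnostics.

    ``params[name]`` has shape (n_chains, n_draws); ``N`` likewise.  Activity
    centers ``s`` (n_chains, n_stored, M, 2), inclusion ``z`` and latent sex
    (n_chains, n_stored, M) are stored every ``s_stride`` kept draws.
    """

    params: dict
    N: np.ndarray
    s: np.ndarray
    z: np.ndarray
    sex: np.ndarray
    s_stride: int
    accept_rates: list
    M: int
    n_obs: int
    scaling: CovariateScaling
    config: MCMCConfig
    priors: Priors
    effects: tuple

    @property
    def n_chains(self) -> int:
        return self.N.shape[0]

    @property
    def n_draws(self) -> int:
        return self.N.shape[1]

    def draws(self, name: str) -> np.ndarray:
        """All chains pooled, for a parameter name, 'N', 'sigma' (km),
        'sigma_male' or 'lambda0' (natural scale)."""
        if name == "N":
            return self.N.reshape(-1)
        if name == "lambda0":
            return np.exp(self.params["log_lambda0"].reshape(-1))
        if name == "sigma":
            return np.exp(self.params["log_sigma0"].reshape(-1))
        if name == "sigma_male":
            return np.exp(
                (self.params["log_sigma0"] + self.params["beta_sigma_sex"]).reshape(-1)
            )
        return self.params[name].reshape(-1)

    def chains(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) array for a parameter name or 'N'."""
        if name == "N":
            return self.N.astype(float)
        return self.params[name]

    def sampled_param_names(self) -> list:
        """Names of parameters actually updated (non-constant chains)."""
        out = []
        for name in PARAM_NAMES:
            arr = self.params[name]
            if np.ptp(arr) > 0:
                out.append(name)
        return out

    def rhat(self, name: str) -> float:
        return gelman_rubin(self.chains(name))

    def rhat_table(self) -> dict:
        """Split Gelman-Rubin statistic per sampled parameter (plus N)."""
        tab = {name: self.rhat(name) for name in self.sampled_param_names()}
        tab["N"] = self.rhat("N")
        return tab

    def to_csv(self, outdir) -> None:
        """One CSV per chain: iteration, each parameter, N."""
        import pandas as pd
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            df = pd.DataFrame({name: self.params[name][c] for name in PARAM_NAMES})
            df.insert(0, "iteration", np.arange(self.n_draws))
            df["N"] = self.N[c]
            df.to_csv(outdir / f"posterior_chain{c + 1}.csv", index=False)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split potential scale reduction factor (split R-hat).

    ``chains`` has shape (n_chains, n_draws) with >= 2 chains and >= 10 draws
    each.  Each chain is split in half; R-hat compares between- and
    within-half variances.  Returns 1.0 by convention when all draws are
    identical (both variance components zero).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains of draws")
    if x.shape[1] < 10:
        raise ValueError("R-hat needs at least 10 draws per chain")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Multi-chain effective sample size (Geyer initial positive sequence)."""
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 4:
        return float(m * n)
    xc = x - x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, ddof=0).mean()
    if var == 0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho = np.zeros(max_lag)
    for t in range(1, max_lag + 1):
        rho[t - 1] = np.mean(
            [np.dot(xc[c, :-t], xc[c, t:]) / n for c in range(m)]
        ) / var
    tau = 1.0
    for t in range(0, max_lag - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(m * n / tau)


def _initial_state(data, grid, scaling, M, rng, use_size):
    """Overdispersed but data-informed chain initialization."""
    n_obs = data.n_individuals
    centers = grid.cell_centers

    sx = np.empty(M)
    sy = np.empty(M)
    # observed: modal capture cell center (guaranteed inside S) + in-cell jitter
    for i in range(n_obs):
        counts = data.y[i].sum(axis=1)
        j = int(np.argmax(counts))
        sx[i] = centers[j, 0] + rng.uniform(-0.4, 0.4) * grid.cell_size
        sy[i] = centers[j, 1] + rng.uniform(-0.4, 0.4) * grid.cell_size
    if M > n_obs:
        pts = grid.sample_uniform(rng, M - n_obs)
        sx[n_obs:] = pts[:, 0]
        sy[n_obs:] = pts[:, 1]

    z = np.ones(M, dtype=np.uint8)
    z[n_obs:] = (rng.random(M - n_obs) < 0.5).astype(np.uint8)

    sex = np.full(M, -1.0)
    sex[:n_obs] = data.sex.astype(float)
    latent = sex < 0
    sex[latent] = (rng.random(int(latent.sum())) < 0.45).astype(float)

    size = np.zeros(M)
    size[:n_obs] = np.where(np.isfinite(scaling.size_std), scaling.size_std, 0.0)

    # sigma init from the spread of multi-cell captures (E|d| = sigma*sqrt(pi)
    # between two independent bivariate-normal positions)
    dists = []
    for i in range(n_obs):
        caught = np.nonzero(data.y[i].sum(axis=1) > 0)[0]
        if caught.size >= 2:
            pc = centers[caught]
            dd = np.sqrt(((pc[:, None, :] - pc[None, :, :]) ** 2).sum(-1))
            dists.append(dd[np.triu_indices(caught.size, 1)].mean())
    if dists:
        sig0 = max(grid.cell_size / 4.0, float(np.mean(dists)) / np.sqrt(np.pi))
    else:
        sig0 = grid.cell_size
    lsig0 = np.log(sig0 * rng.uniform(0.6, 1.6))

    # lambda0 init from the mean encounter count per observed individual
    mean_enc = max(data.n_encounters / max(n_obs, 1), 0.05)
    kernel_mass = 2 * np.pi * np.exp(2 * lsig0) / grid.cell_area
    slots = float(data.sampled.sum()) / grid.n_cells  # sampled occasions per cell
    ll0 = np.log(mean_enc / max(kernel_mass * slots, 1e-3)) + rng.normal(0, 0.5)
    ll0 = float(np.clip(ll0, -10, 3))

    params0 = np.zeros(6)
    params0[0] = ll0
    params0[4] = lsig0
    return sx, sy, z, sex, size, params0


def run_chains(
    data: EncounterData,
    grid: StudyGrid,
    config: MCMCConfig | None = None,
    priors: Priors | None = None,
    effects: tuple = ("effort", "sex", "size"),
    sex_sigma: bool = True,
    scaling: CovariateScaling | None = None,
    fixed_params: dict | None = None,
) -> PosteriorSamples:
    """Run the full MCMC and return posterior samples.

    ``effects`` selects which covariates enter the log-hazard linear
    predictor; ``sex_sigma`` adds the male offset on log sigma.
    ``fixed_params`` pins named parameters at given values (their update is
    skipped) — used by oracle tests with sigma fixed.
    """
    config = config or MCMCConfig()
    priors = priors or Priors()
    data.validate_against_grid(grid)
    n_obs = data.n_individuals

    if scaling is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaling = standardize_covariates(data.effort, data.size)

    use_eff = ("effort" in effects) and not scaling.effort_degenerate
    use_sex = "sex" in effects
    use_size = ("size" in effects) and not scaling.size_degenerate
    if ("effort" in effects) and scaling.effort_degenerate:
        warnings.warn("effort covariate degenerate; beta_effort held at 0", stacklevel=2)
    if ("size" in effects) and scaling.size_degenerate:
        warnings.warn("size covariate degenerate; beta_size held at 0", stacklevel=2)
    use_sigsex = bool(sex_sigma)

    M = config.M if config.M is not None else 8 * max(n_obs, 1)
    if M <= n_obs:
        raise ValueError(f"augmented size M={M} must exceed n_obs={n_obs}")

    obs_sizes = scaling.size_std[np.isfinite(scaling.size_std)]
    if obs_sizes.size:
        size_lo, size_hi = float(obs_sizes.min()), float(obs_sizes.max())
    else:
        size_lo, size_hi = -3.0, 3.0
        use_size = False

    # sparse encounter structure (CSR over individuals)
    ones_ptr = np.zeros(n_obs + 1, dtype=np.int64)
    cell_list, occ_list = [], []
    for i in range(n_obs):
        jj, kk = np.nonzero(data.y[i])
        ones_ptr[i + 1] = ones_ptr[i] + jj.size
        cell_list.append(jj)
        occ_list.append(kk)
    ones_cell = (
        np.concatenate(cell_list).astype(np.int64) if cell_list else np.zeros(0, np.int64)
    )
    ones_occ = (
        np.concatenate(occ_list).astype(np.int64) if occ_list else np.zeros(0, np.int64)
    )

    sex_obs = np.full(M, -1, dtype=np.int8)
    sex_obs[:n_obs] = data.sex
    size_obs = np.full(M, np.nan)
    size_obs[:n_obs] = scaling.size_std

    fixed = dict(fixed_params or {})
    steps0 = np.array(
        [config.step_s] + [config.step_param] * 6 + [config.step_size_latent]
    )
    # pinning a parameter: zero proposal step and matching init
    pin_idx = {name: k for k, name in enumerate(PARAM_NAMES[:6])}
    for name in fixed:
        if name not in pin_idx:
            raise ValueError(f"cannot fix parameter {name!r}")

    cellx = np.ascontiguousarray(grid.cell_centers[:, 0])
    celly = np.ascontiguousarray(grid.cell_centers[:, 1])
    x0, y0 = grid.origin
    lat2act = grid._lattice_to_active

    n_keep = (config.n_iter - config.n_burn + config.thin - 1) // config.thin
    all_params = np.zeros((config.n_chains, n_keep, 8))
    all_N = np.zeros((config.n_chains, n_keep), dtype=np.int64)
    all_s = None
    all_z = None
    all_sex = None
    rates_list = []

    for c in range(config.n_chains):
        chain_seed = int(config.seed + c) & 0x7FFFFFFF
        rng = np.random.default_rng(chain_seed)
        sx, sy, z0, sex0, size0, params0 = _initial_state(
            data, grid, scaling, M, rng, use_size
        )
        steps = steps0.copy()
        for name, val in fixed.items():
            k = pin_idx[name]
            params0[k] = val
            steps[k + 1] = 0.0  # proposal slots are offset by the s-update slot
        # zero-step proposals never move; mark unused effects off entirely
        out = _mcmc.run_chain(
            chain_seed,
            config.n_iter,
            config.n_burn,
            config.thin,
            config.s_thin,
            M,
            n_obs,
            cellx,
            celly,
            float(x0),
            float(y0),
            float(grid.cell_size),
            grid.nx,
            grid.ny,
            lat2act,
            np.ascontiguousarray(scaling.effort_std),
            np.ascontiguousarray(data.sampled.astype(np.uint8)),
            ones_ptr,
            ones_cell,
            ones_occ,
            sex_obs,
            size_obs,
            np.uint8(use_eff and "beta_effort" not in fixed),
            np.uint8(use_sex and "beta_sex" not in fixed),
            np.uint8(use_size and "beta_size" not in fixed),
            np.uint8(use_sigsex and "beta_sigma_sex" not in fixed),
            size_lo,
            size_hi,
            priors.mu_log_lambda0,
            priors.sd_log_lambda0,
            priors.sd_beta,
            priors.sigma_range[0],
            priors.sigma_range[1],
            params0,
            0.5,
            0.45,
            sx,
            sy,
            z0,
            sex0,
            size0,
            steps,
            config.adapt_every,
        )
        params_c, N_c, sx_c, sy_c, z_c, sexdraw_c, rates, _ = out
        # a pinned sigma must still be honoured even with its update disabled
        all_params[c] = params_c
        all_N[c] = N_c
        if all_s is None:
            n_keep_s = sx_c.shape[0]
            all_s = np.zeros((config.n_chains, n_keep_s, M, 2), dtype=np.float32)
            all_z = np.zeros((config.n_chains, n_keep_s, M), dtype=np.uint8)
            all_sex = np.zeros((config.n_chains, n_keep_s, M), dtype=np.uint8)
        all_s[c, :, :, 0] = sx_c
        all_s[c, :, :, 1] = sy_c
        all_z[c] = z_c
        all_sex[c] = sexdraw_c
        rates_list.append(dict(zip(PROPOSAL_NAMES, rates.tolist())))

    params = {name: all_params[:, :, k] for k, name in enumerate(PARAM_NAMES)}
    post = PosteriorSamples(
        params=params,
        N=all_N,
        s=all_s,
        z=all_z,
        sex=all_sex,
        s_stride=config.s_thin,
        accept_rates=rates_list,
        M=M,
        n_obs=n_obs,
        scaling=scaling,
        config=config,
        priors=priors,
        effects=tuple(e for e, u in
                      (("effort", use_eff), ("sex", use_sex), ("size", use_size))
                      if u) + (("sex_sigma",) if use_sigsex else ()),
    )
    frac_at_M = float(np.mean(all_N == M))
    if frac_at_M >= 0.01:
        warnings.warn(
            f"posterior puts {frac_at_M:.1%} of its mass at N = M = {M}; "
            "increase the augmented size M",
            stacklevel=2,
        )
    return post


def update_inclusion(E: np.ndarray, psi: float, rng: np.random.Generator) -> np.ndarray:
    """Exact Bernoulli full-conditional draw of inclusion indicators for
    unobserved individuals: odds(z=1) = psi * exp(-E) vs (1 - psi).

    ``E`` is each individual's total expected hazard over sampled
    cell-occasions.  Exposed for direct testing; the jitted sampler performs
    the identical update in-line.
    """
    lodds = np.log(psi / (1.0 - psi)) - np.asarray(E, dtype=float)
    p1 = 1.0 / (1.0 + np.exp(-lodds))
    return (rng.random(p1.shape) < p1).astype(np.int8)
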