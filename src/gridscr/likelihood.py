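"""The SCR probability model as pure functions.

Each individual i has a latent activity center ``s_i`` with a Uniform(S)
prior.  The expected number of captures of i in cell j on occasion k is a
Gaussian hazard,

    lambda_ijk = exp(log lambda0 + b_eff * effort_jk + b_sex * sex_i
                     + b_size * size_i) * exp(-d_ij^2 / (2 sigma_i^2)),

with d_ij the Euclidean distance between the activity center and the cell
center, and sigma possibly sex-specific via a log-linear offset.  Encounters
are binarized per (individual, cell, occasion), so the observation model is
Bernoulli with p = 1 - exp(-lambda), which reduces to lambda when hazards are
small.  Cell-occasions with zero fishing effort have p = 0 exactly.

Population size is handled by data augmentation: the encounter array is padded
to M rows with all-zero histories and inclusion indicators z_i ~ Bernoulli(psi);
N = sum(z) is a derived quantity.  Sex and size of uncaptured (and unrecorded)
individuals are latent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SCRParams",
    "AugmentedState",
    "CovariateScaling",
    "hazard_rate",
    "encounter_prob",
    "standardize_covariates",
    "complete_data_loglik",
]


@dataclass
class SCRParams:
    """Parameters of the grid-cell SCR encounter model.

    ``log_lambda0`` is the log baseline encounter hazard per occasion for an
    average-effort cell (covariates at 0); slopes are per standardized unit of
    their covariate; ``beta_sex`` and ``beta_sigma_sex`` are male offsets
    (female = 0, male = 1) on the log hazard and log range respectively.
    ``psi`` is the data-augmentation inclusion probability and ``psi_sex``
    the proportion of the population that is male.
    """

    log_lambda0: float = 0.0
    beta_effort: float = 0.0
    beta_sex: float = 0.0
    beta_size: float = 0.0
    log_sigma0: float = 0.0
    beta_sigma_sex: float = 0.0
    psi: float = 0.5
    psi_sex: float = 0.5

    def __post_init__(self):
        for name in ("psi", "psi_sex"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not np.isfinite(
            [self.log_lambda0, self.beta_effort, self.beta_sex, self.beta_size,
             self.log_sigma0, self.beta_sigma_sex]
        ).all():
            raise ValueError("non-finite parameter value")

    @property
    def lambda0(self) -> float:
        return float(np.exp(self.log_lambda0))

    def sigma(self, sex=0) -> float | np.ndarray:
        """Range parameter sigma (km) for the given sex code(s)."""
        s = np.exp(self.log_sigma0 + self.beta_sigma_sex * np.asarray(sex, float))
        return float(s) if s.ndim == 0 else s

    def replace(self, **kw) -> "SCRParams":
        return replace(self, **kw)


@dataclass
class AugmentedState:
    """Latent state of the augmented population of size M.

    ``s`` are activity centers (M, 2) in km; ``z`` the inclusion indicators;
    ``sex`` and ``size_std`` carry observed values where recorded and imputed
    values (current MCMC state, or truth in simulations) elsewhere.
    """

    s: np.ndarray
    z: np.ndarray
    sex: np.ndarray
    size_std: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.size_std = np.asarray(self.size_std, dtype=float)
        M = self.s.shape[0]
        if self.s.shape != (M, 2):
            raise ValueError("s must have shape (M, 2)")
        for arr, name in ((self.z, "z"), (self.sex, "sex"), (self.size_std, "size_std")):
            if arr.shape != (M,):
                raise ValueError(f"{name} must have shape (M,)")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must be binary")

    @property
    def M(self) -> int:
        return self.s.shape[0]

    @property
    def N(self) -> int:
        """Realized population size, sum of inclusion indicators."""
        return int(self.z.sum())


def hazard_rate(d, params: SCRParams, effort_std=0.0, sex=0, size_std=0.0):
    """Expected captures per occasion at distance d (km) from the activity center.

    Vectorized over any broadcastable combination of inputs.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    sig = params.sigma(sex)
    if np.any(np.asarray(sig) <= 0):
        raise ValueError("sigma must be positive")
    loglin = (
        params.log_lambda0
        + params.beta_effort * np.asarray(effort_std, float)
        + params.beta_sex * np.asarray(sex, float)
        + params.beta_size * np.asarray(size_std, float)
    )
    lam = np.exp(loglin - d**2 / (2.0 * sig**2))
    return float(lam) if lam.ndim == 0 else lam


def encounter_prob(lam):
    """Bernoulli encounter probability p = 1 - exp(-lambda) from a hazard."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("hazard must be non-negative")
    p = -np.expm1(-lam)
    return float(p) if p.ndim == 0 else p


@dataclass
class CovariateScaling:
    """Standardization applied to effort and size before model fitting.

    Effort (days fished) is z-scored over *sampled* cell-occasions only, so
    the baseline rate refers to the average realized fishing effort; size
    (fork length, cm) is z-scored over individuals with a recorded length.
    Sample (ddof=1) standard deviations are used.  A zero-variance covariate
    is centered only (scale 1) and its slope should be held at 0.
    """

    effort_std: np.ndarray
    size_std: np.ndarray
    effort_mean: float
    effort_sd: float
    size_mean: float
    size_sd: float
    effort_degenerate: bool = False
    size_degenerate: bool = False


def standardize_covariates(effort: np.ndarray, size: np.ndarray) -> CovariateScaling:
    """Standardize the effort surface and individual sizes.

    Parameters
    ----------
    effort : (J, K) days fished per cell-occasion (zeros = not sampled).
    size : (n,) fork lengths in cm, NaN where unrecorded.
    """
    effort = np.asarray(effort, dtype=float)
    size = np.asarray(size, dtype=float)
    sampled = effort > 0
    if not sampled.any():
        raise ValueError("no positive effort anywhere")
    vals = effort[sampled]
    emean = float(vals.mean())
    esd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    edeg = not (esd > 0)
    if edeg:
        warnings.warn(
            "effort has zero variance over sampled cell-occasions; centering only "
            "(hold beta_effort at 0)",
            stacklevel=2,
        )
        esd = 1.0
    effort_std = np.zeros_like(effort)
    effort_std[sampled] = (effort[sampled] - emean) / esd

    obs = np.isfinite(size)
    if obs.any():
        smean = float(size[obs].mean())
        ssd = float(size[obs].std(ddof=1)) if obs.sum() > 1 else 0.0
    else:
        smean, ssd = 0.0, 0.0
    sdeg = not (ssd > 0)
    if sdeg and obs.sum() > 1:
        warnings.warn(
            "size has zero variance; centering only (hold beta_size at 0)",
            stacklevel=2,
        )
    if not (ssd > 0):
        ssd = 1.0
    size_std = (size - smean) / ssd
    return CovariateScaling(effort_std, size_std, emean, esd, smean, ssd, edeg, sdeg)


def complete_data_loglik(
    data,
    state: AugmentedState,
    params: SCRParams,
    grid,
    scaling: CovariateScaling | None = None,
    include_aug_priors: bool = False,
) -> float:
    """Complete-data log likelihood of the augmented binary encounter model.

    ``data`` is an :class:`~gridscr.data.EncounterData` holding the observed
    rows of y (n_obs <= M); rows beyond n_obs are the augmented all-zero
    histories.  Individual covariates are taken from ``state`` (which carries
    observed values where recorded and the current imputations elsewhere), so
    the same function scores both real and latent covariates.  Effort enters
    standardized (``scaling`` defaults to :func:`standardize_covariates` on
    the data); p = 0 exactly wherever raw effort is zero.

    With ``include_aug_priors`` the Bernoulli(psi) terms for z and the
    Bernoulli(psi_sex) terms for sex (over included individuals) are added.

    Returns -inf (with a warning) if y = 1 occurs in an unsampled
    cell-occasion, which is impossible under the model.
    """
    y = np.asarray(data.y)
    cell_centers = np.asarray(grid.cell_centers, dtype=float)
    M = state.M
    n_obs, J, K = y.shape
    if n_obs > M:
        raise ValueError("more observed rows than augmented size M")
    if cell_centers.shape[0] != J:
        raise ValueError("grid does not match encounter data")
    if scaling is None:
        scaling = standardize_covariates(data.effort, data.size)
    eff = scaling.effort_std
    sampled = data.effort > 0

    if np.any(y[:, ~sampled] != 0):
        warnings.warn("encounter recorded in a zero-effort cell-occasion", stacklevel=2)
        return -np.inf

    d2 = (
        (state.s[:, 0:1] - cell_centers[None, :, 0]) ** 2
        + (state.s[:, 1:2] - cell_centers[None, :, 1]) ** 2
    )  # (M, J)
    sig = np.exp(params.log_sigma0 + params.beta_sigma_sex * state.sex.astype(float))
    kern = -d2 / (2.0 * sig[:, None] ** 2)  # (M, J)
    per_i = params.beta_sex * state.sex.astype(float) + params.beta_size * state.size_std
    loglam = (
        params.log_lambda0
        + per_i[:, None, None]
        + kern[:, :, None]
        + params.beta_effort * eff[None, :, :]
    )  # (M, J, K)
    lam = np.exp(loglam)

    yfull = np.zeros((M, J, K), dtype=y.dtype)
    yfull[:n_obs] = y
    zmask = state.z.astype(bool)

    # log(1 - p) = -lam; log p = log(1 - exp(-lam)) = log(-expm1(-lam))
    with np.errstate(divide="ignore"):
        logp = np.log(-np.expm1(-lam))
    ll_terms = np.where(yfull == 1, logp, -lam)
    ll_terms = np.where(sampled[None, :, :], ll_terms, 0.0)
    ll = float(ll_terms[zmask].sum())

    if include_aug_priors:
        nz = int(state.z.sum())
        ll += nz * np.log(params.psi) + (M - nz) * np.log(1.0 - params.psi)
        sex_z = state.sex[zmask].astype(float)
        ll += float(
            np.sum(sex_z * np.log(params.psi_sex) + (1 - sex_z) * np.log(1 - params.psi_sex))
        )
    return ll
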