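"""Derived ecological quantities from SCR posterior samples.

Abundance N is the posterior of the summed inclusion indicators.  Density
divides N by the *area occupied* by the population: per posterior draw, the
union of each included individual's 99% activity-space circle (radius
``sigma * sqrt(-2 ln(1-q))``, sex-specific sigma) intersected with the state
space S, evaluated on a fine raster.  The activity space of a circular
bivariate normal has closed-form q-quantile area ``-2 pi sigma^2 ln(1-q)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import StudyGrid
from .sampler import PosteriorSamples

__all__ = [
    "AbundanceSummary",
    "DensitySurface",
    "TrendEstimate",
    "TagRetention",
    "abundance",
    "activity_area",
    "density",
    "trend",
    "interaction_fraction",
    "tag_retention",
]


@dataclass
class AbundanceSummary:
    """Posterior summary of population size."""

    mean: float
    median: float
    ci: tuple[float, float]
    draws: np.ndarray = field(repr=False)

    def __str__(self):
        return f"N = {self.mean:.0f} (95% CI {self.ci[0]:.0f}, {self.ci[1]:.0f})"


@dataclass
class DensitySurface:
    """Per-cell activity-center intensity and overall density.

    ``cell_mean``/``cell_lo``/``cell_hi`` are sharks/km^2 per grid cell
    (posterior mean and central 95% interval of the per-cell activity-center
    count divided by cell area).  ``d_mean``/``d_ci`` summarize overall
    density N / occupied-area per draw; ``d_state_space`` uses the fixed
    area(S) denominator instead.
    """

    cell_mean: np.ndarray
    cell_lo: np.ndarray
    cell_hi: np.ndarray
    d_mean: float
    d_ci: tuple[float, float]
    occupied_area_mean: float
    d_state_space_mean: float
    d_state_space_ci: tuple[float, float]
    area_S: float
    quantile: float
    d_draws: np.ndarray = field(repr=False)
    area_draws: np.ndarray = field(repr=False)
    N_draws: np.ndarray = field(repr=False)

    def __str__(self):
        return (
            f"D = {self.d_mean:.1f} sharks/km^2 "
            f"(95% CI {self.d_ci[0]:.1f}, {self.d_ci[1]:.1f})"
        )


@dataclass
class TrendEstimate:
    """Posterior of a linear abundance trend over occasions."""

    slope_mean: float
    slope_ci: tuple[float, float]
    stable: bool
    slope_draws: np.ndarray = field(repr=False)


@dataclass
class TagRetention:
    """Tag-loss assessment from double-tagging."""

    n_recaptured: int
    n_both_intact: int
    loss_mle: float
    loss_upper: float
    conf: float


def abundance(post: PosteriorSamples) -> AbundanceSummary:
    """Posterior mean/median and central 95% credible interval of N."""
    draws = post.draws("N").astype(float)
    if draws.size == 0:
        raise ValueError("empty posterior")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return AbundanceSummary(float(draws.mean()), float(np.median(draws)), (float(lo), float(hi)), draws)


def activity_area(sigma, q: float = 0.99):
    """Area (km^2) of the q-probability circle of a circular bivariate normal.

    The squared radial distance is sigma^2 * chi^2_2, so the q-quantile radius
    is sigma * sqrt(-2 ln(1-q)) and the area is -2 pi sigma^2 ln(1-q).
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    a = -2.0 * np.pi * sigma**2 * np.log1p(-q)
    return float(a) if a.ndim == 0 else a


def _raster_points(grid: StudyGrid, raster_km: float) -> np.ndarray:
    xmin, xmax, ymin, ymax = grid.bounding_extent
    xs = np.arange(xmin + raster_km / 2, xmax, raster_km)
    ys = np.arange(ymin + raster_km / 2, ymax, raster_km)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    return pts[grid.contains(pts[:, 0], pts[:, 1])]


def density(
    post: PosteriorSamples,
    grid: StudyGrid,
    q: float = 0.99,
    raster_km: float = 0.1,
    max_draws: int | None = 200,
) -> DensitySurface:
    """Density surface and overall density from stored activity centers.

    Uses the thinned activity-center draws.  Per draw the occupied area is
    the raster-evaluated union of q-quantile circles (sex-specific radius)
    around included activity centers, intersected with S; overall density is
    N / occupied-area, so density x area = N holds exactly per draw.
    """
    if post.s is None or post.s.size == 0:
        raise ValueError("no stored activity-center draws")
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    C, nS, M, _ = post.s.shape
    stride = post.s_stride
    pts = _raster_points(grid, raster_km)
    rmult = np.sqrt(-2.0 * np.log1p(-q))

    # draw indices in the full kept-draw arrays matching stored centers
    lsig0 = post.params["log_sigma0"]
    bsigsex = post.params["beta_sigma_sex"]

    flat = [(c, k) for c in range(C) for k in range(nS)]
    if max_draws is not None and len(flat) > max_draws:
        sel = np.linspace(0, len(flat) - 1, max_draws).astype(int)
        flat = [flat[i] for i in sel]

    counts = np.zeros((len(flat), grid.n_cells))
    areas = np.empty(len(flat))
    Ns = np.empty(len(flat), dtype=np.int64)
    skipped = 0
    for t, (c, k) in enumerate(flat):
        kd = k * stride  # index into kept parameter draws
        zmask = post.z[c, k].astype(bool)
        if not zmask.any():
            skipped += 1
            areas[t] = np.nan
            Ns[t] = 0
            continue
        centers = post.s[c, k][zmask].astype(float)
        sexes = post.sex[c, k][zmask]
        sig_f = np.exp(lsig0[c, kd])
        sig_m = np.exp(lsig0[c, kd] + bsigsex[c, kd])
        occupied = np.zeros(pts.shape[0], dtype=bool)
        for sexcode, sig in ((0, sig_f), (1, sig_m)):
            sub = centers[sexes == sexcode]
            if sub.shape[0] == 0:
                continue
            tree = cKDTree(sub)
            dmin, _ = tree.query(pts, k=1)
            occupied |= dmin <= sig * rmult
        areas[t] = occupied.sum() * raster_km**2
        Ns[t] = centers.shape[0]
        cellidx = grid.assign(centers[:, 0], centers[:, 1])
        counts[t] = np.bincount(cellidx[cellidx >= 0], minlength=grid.n_cells)
    if skipped:
        warnings.warn(f"{skipped} draws had no included individuals; skipped", stacklevel=2)
    ok = np.isfinite(areas)
    d_draws = Ns[ok] / areas[ok]
    surface = counts[ok] / grid.cell_area
    lo, hi = np.percentile(d_draws, [2.5, 97.5])
    dS = Ns[ok] / grid.total_area
    dSlo, dShi = np.percentile(dS, [2.5, 97.5])
    cl, ch = np.percentile(surface, [2.5, 97.5], axis=0)
    return DensitySurface(
        cell_mean=surface.mean(axis=0),
        cell_lo=cl,
        cell_hi=ch,
        d_mean=float(d_draws.mean()),
        d_ci=(float(lo), float(hi)),
        occupied_area_mean=float(areas[ok].mean()),
        d_state_space_mean=float(dS.mean()),
        d_state_space_ci=(float(dSlo), float(dShi)),
        area_S=grid.total_area,
        quantile=q,
        d_draws=d_draws,
        area_draws=areas[ok],
        N_draws=Ns[ok],
    )


def trend(N_draws: np.ndarray, times=None, level: float = 0.95) -> TrendEstimate:
    """Posterior of the linear slope of abundance over occasions.

    ``N_draws`` has shape (n_draws, n_occasions): each row is one joint
    posterior draw of the per-occasion abundance series (draws from
    independent per-occasion fits are paired by index).  The population is
    declared stable when the central credible interval contains 0.
    """
    N_draws = np.asarray(N_draws, dtype=float)
    if N_draws.ndim != 2 or N_draws.shape[1] < 3:
        raise ValueError("need draws for at least 3 occasions")
    T = N_draws.shape[1]
    t = np.arange(T, dtype=float) if times is None else np.asarray(times, dtype=float)
    tc = t - t.mean()
    denom = float((tc**2).sum())
    slopes = (N_draws * tc).sum(axis=1) / denom
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(slopes, [a, 100 - a])
    return TrendEstimate(
        slope_mean=float(slopes.mean()),
        slope_ci=(float(lo), float(hi)),
        stable=bool(lo <= 0.0 <= hi),
        slope_draws=slopes,
    )


def interaction_fraction(n_unique_observed: int, post: PosteriorSamples):
    """Fraction of the population handled at least once: n_unique / N per draw.

    Returns (mean, (lo, hi), draws).
    """
    if n_unique_observed < 0:
        raise ValueError("count must be non-negative")
    N = post.draws("N").astype(float)
    if np.any(N < n_unique_observed):
        raise ValueError("posterior draw with N below the number of observed individuals")
    if n_unique_observed == 0:
        return 0.0, (0.0, 0.0), np.zeros_like(N)
    fr = n_unique_observed / N
    lo, hi = np.percentile(fr, [2.5, 97.5])
    return float(fr.mean()), (float(lo), float(hi)), fr


def tag_retention(
    n_double_recaptured: int, n_both_intact: int, conf: float = 0.95
) -> TagRetention:
    """Per-recapture probability of having lost at least one tag.

    MLE is ``1 - n_both/n``; the one-sided upper confidence bound is the
    exact (Clopper-Pearson) binomial bound, which for zero observed losses
    solves ``(1 - p_U)^n = 1 - conf``.
    """
    n, x_intact = n_double_recaptured, n_both_intact
    if n <= 0:
        raise ValueError("no double-tagged recaptures: tag loss is not estimable")
    if not (0 <= x_intact <= n):
        raise ValueError("intact count must lie in [0, n]")
    losses = n - x_intact
    mle = losses / n
    upper = float(stats.beta.ppf(conf, losses + 1, n - losses))
    return TagRetention(n, x_intact, float(mle), upper, conf)
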