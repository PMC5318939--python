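"""Results object: posterior summaries, derived estimators, diagnostics, plots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimates
from .sampler import PARAM_NAMES, PosteriorSamples, effective_sample_size, gelman_rubin

__all__ = ["SCRResults"]


class SCRResults:
    """Posterior results of a fitted grid-cell SCR model.

    Carries the :class:`~gridscr.sampler.PosteriorSamples` and exposes the
    derived ecological estimators (abundance, density, activity space,
    interaction fraction), convergence diagnostics and a printable summary.
    """

    def __init__(self, model, post: PosteriorSamples):
        self.model = model
        self.post = post

    # -- diagnostics ------------------------------------------------------
    def rhat(self) -> dict:
        """Split Gelman-Rubin R-hat per sampled parameter (and N)."""
        return self.post.rhat_table()

    def max_rhat(self, include: tuple = ("sigma", "lambda0", "beta")) -> float:
        """Maximum R-hat over the named parameter groups.

        ``sigma`` covers log_sigma0 (and beta_sigma_sex if sampled),
        ``lambda0`` the baseline log rate, ``beta`` all covariate slopes.
        """
        names = []
        sampled = self.post.sampled_param_names()
        if "sigma" in include:
            names += [n for n in ("log_sigma0", "beta_sigma_sex") if n in sampled]
        if "lambda0" in include and "log_lambda0" in sampled:
            names.append("log_lambda0")
        if "beta" in include:
            names += [
                n for n in ("beta_effort", "beta_sex", "beta_size") if n in sampled
            ]
        if not names:
            raise ValueError("no sampled parameters in the requested groups")
        return max(gelman_rubin(self.post.chains(n)) for n in names)

    def converged(self, threshold: float = 1.1) -> bool:
        """The conventional criterion: all R-hat below 1.1."""
        return self.max_rhat() < threshold

    def ess(self) -> dict:
        return {
            name: effective_sample_size(self.post.chains(name))
            for name in self.post.sampled_param_names() + ["N"]
        }

    # -- derived quantities ----------------------------------------------
    def abundance(self) -> estimates.AbundanceSummary:
        return estimates.abundance(self.post)

    def activity_space(self, q: float = 0.99) -> dict:
        """Posterior mean and 95% CI of the q-quantile activity-space area
        (km^2), by sex when sigma is sex-specific."""
        out = {}
        groups = {"female": "sigma"}
        if "beta_sigma_sex" in self.post.sampled_param_names():
            groups["male"] = "sigma_male"
        else:
            groups = {"all": "sigma"}
        for label, name in groups.items():
            a = estimates.activity_area(self.post.draws(name), q)
            lo, hi = np.percentile(a, [2.5, 97.5])
            out[label] = {"mean": float(a.mean()), "ci": (float(lo), float(hi))}
        return out

    def density(self, q: float = 0.99, raster_km: float = 0.1, max_draws: int = 200):
        return estimates.density(
            self.post, self.model.grid, q=q, raster_km=raster_km, max_draws=max_draws
        )

    def interaction_fraction(self, n_unique: int | None = None):
        n = self.post.n_obs if n_unique is None else n_unique
        return estimates.interaction_fraction(n, self.post)

    # -- parameter table --------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        rows = []
        sampled = self.post.sampled_param_names()
        show = sampled + ["N"]
        multi = self.post.n_chains >= 2
        for name in show:
            d = self.post.draws(name)
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "2.5%": lo,
                    "97.5%": hi,
                    "rhat": self.post.rhat(name) if multi else np.nan,
                }
            )
        # natural-scale conveniences
        for name, src in (("lambda0", "lambda0"), ("sigma_km", "sigma")):
            d = self.post.draws(src)
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "2.5%": lo,
                    "97.5%": hi,
                    "rhat": np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        """Printable summary in the style of the field's reporting
        (abundance to the individual, density to 0.1 sharks/km^2)."""
        ab = self.abundance()
        lines = [
            "Grid-cell spatial capture-recapture fit",
            "=" * 54,
            f"observed individuals: {self.post.n_obs}   augmented M: {self.post.M}",
            f"chains: {self.post.n_chains}   kept draws/chain: {self.post.n_draws}",
            "",
            self.params_frame().round(4).to_string(),
            "",
            f"Abundance: {ab}",
        ]
        if self.post.n_chains >= 2:
            lines.append(
                f"max R-hat (sigma, lambda0, betas): {self.max_rhat():.4f} "
                f"({'<' if self.converged() else '>='} 1.1)"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<SCRResults: {self.post.n_chains} chains x {self.post.n_draws} draws, "
            f"n_obs={self.post.n_obs}, M={self.post.M}>"
        )

    # -- export -----------------------------------------------------------
    def to_csv(self, outdir) -> None:
        """Posterior CSV per chain plus a JSON diagnostics report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.post.to_csv(outdir)
        report = {
            "rhat": self.rhat() if self.post.n_chains >= 2 else None,
            "ess": self.ess(),
            "accept_rates": self.post.accept_rates,
            "n_obs": self.post.n_obs,
            "M": self.post.M,
        }
        (outdir / "diagnostics.json").write_text(json.dumps(report, indent=2))

    def density_to_csv(self, path, q: float = 0.99, **kw) -> None:
        surf = self.density(q=q, **kw)
        grid = self.model.grid
        df = pd.DataFrame(
            {
                "cell_id": np.arange(1, grid.n_cells + 1),
                "x": grid.cell_centers[:, 0],
                "y": grid.cell_centers[:, 1],
                "D_mean": surf.cell_mean,
                "D_lo": surf.cell_lo,
                "D_hi": surf.cell_hi,
            }
        )
        df.to_csv(path, index=False)

    # -- plotting ----------------------------------------------------------
    def plot_trace(self, names=None, axes=None):
        """Trace plots per chain for the sampled parameters."""
        import matplotlib.pyplot as plt

        names = names or self.post.sampled_param_names() + ["N"]
        if axes is None:
            fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)), squeeze=False)
            axes = axes[:, 0]
        for ax, name in zip(axes, names):
            for c in range(self.post.n_chains):
                ax.plot(self.post.chains(name)[c], lw=0.5)
            ax.set_ylabel(name)
        return axes

    def plot_density_surface(self, q: float = 0.99, ax=None, **kw):
        """Cell-level posterior-mean density map."""
        import matplotlib.pyplot as plt

        surf = self.density(q=q, **kw)
        grid = self.model.grid
        img = np.full((grid.ny, grid.nx), np.nan)
        ix, iy = grid.lattice_index(
            grid.cell_centers[:, 0], grid.cell_centers[:, 1]
        )
        img[iy, ix] = surf.cell_mean
        if ax is None:
            _, ax = plt.subplots()
        xmin, xmax, ymin, ymax = grid.bounding_extent
        im = ax.imshow(
            img, origin="lower", extent=(xmin, xmax, ymin, ymax), cmap="RdYlGn_r"
        )
        ax.set_xlabel("km east")
        ax.set_ylabel("km north")
        plt.colorbar(im, ax=ax, label="sharks / km$^2$")
        return ax
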