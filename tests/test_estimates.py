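"""Derived estimators: abundance, activity space, density, trend,
interaction fraction, tag retention."""

import numpy as np
import pytest

from gridscr.estimates import (
    abundance,
    activity_area,
    density,
    interaction_fraction,
    tag_retention,
    trend,
)
from gridscr.geometry import build_grid
from gridscr.sampler import PosteriorSamples


def fake_posterior(N_draws, s=None, z=None, sex=None, sigma=1.0, s_stride=1,
                   M=None, n_obs=0):
    """Hand-built PosteriorSamples for estimator unit tests."""
    N_draws = np.atleast_2d(np.asarray(N_draws))
    C, D = N_draws.shape
    params = {
        name: np.zeros((C, D))
        for name in (
            "log_lambda0", "beta_effort", "beta_sex", "beta_size",
            "log_sigma0", "beta_sigma_sex", "psi", "psi_sex",
        )
    }
    params["log_sigma0"] += np.log(sigma)
    params["psi"] += 0.5
    params["psi_sex"] += 0.5
    if s is not None:
        s = np.asarray(s, dtype=np.float32)
        M = s.shape[2]
        z = np.ones((C, s.shape[1], M), np.uint8) if z is None else np.asarray(z, np.uint8)
        sex = np.zeros((C, s.shape[1], M), np.uint8) if sex is None else np.asarray(sex, np.uint8)
    else:
        M = M or int(N_draws.max())
        s = np.zeros((C, 0, M, 2), np.float32)
        z = np.zeros((C, 0, M), np.uint8)
        sex = np.zeros((C, 0, M), np.uint8)
    return PosteriorSamples(
        params=params, N=N_draws.astype(np.int64), s=s, z=z, sex=sex,
        s_stride=s_stride, accept_rates=[], M=M, n_obs=n_obs, scaling=None,
        config=None, priors=None, effects=(),
    )


class TestAbundance:
    def test_degenerate_posterior(self):
        ab = abundance(fake_posterior([[100, 100, 100, 100]]))
        assert ab.mean == 100 and ab.ci == (100.0, 100.0)

    def test_symmetric_draws(self):
        ab = abundance(fake_posterior([[90, 100, 110]]))
        assert ab.mean == pytest.approx(100.0)
        assert ab.median == 100.0


class TestActivityArea:
    def test_unit_sigma_99(self):
        assert activity_area(1.0, 0.99) == pytest.approx(28.934, abs=2e-3)

    def test_matches_reported_female_space(self):
        assert activity_area(0.933, 0.99) == pytest.approx(25.19, abs=0.01)

    def test_vanishes_as_q_to_zero(self):
        assert activity_area(1.0, 1e-12) < 1e-9

    def test_strictly_increasing_in_sigma_and_q(self):
        sig = np.linspace(0.2, 3.0, 30)
        assert np.all(np.diff(activity_area(sig, 0.99)) > 0)
        areas = [activity_area(1.0, q) for q in np.linspace(0.1, 0.999, 30)]
        assert np.all(np.diff(areas) > 0)

    def test_monte_carlo_agreement(self):
        """Closed form vs direct Monte-Carlo integration of the bivariate
        normal: fraction of mass within the q-quantile radius."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(1_000_000, 2))
        r2 = (pts**2).sum(axis=1)
        radius2 = activity_area(1.0, 0.99) / np.pi
        frac = (r2 <= radius2).mean()
        assert frac == pytest.approx(0.99, abs=0.001)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError):
            activity_area(1.0, q)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            activity_area(0.0, 0.99)


class TestDensity:
    def big_grid(self):
        from shapely.geometry import box

        return build_grid(box(0.0, 0.0, 30.0, 30.0), cell_size=2.0)

    def test_single_center_circle_area(self):
        """One included individual in the middle of a large S: density is
        1 / (99% circle area), within raster tolerance."""
        grid = self.big_grid()
        s = np.full((1, 3, 1, 2), 15.0)
        post = fake_posterior([[1, 1, 1]], s=s, sigma=1.0)
        surf = density(post, grid, q=0.99, raster_km=0.1)
        assert surf.occupied_area_mean == pytest.approx(28.934, rel=0.02)
        assert surf.d_mean == pytest.approx(1 / 28.934, rel=0.02)

    def test_saturated_state_space(self):
        """Centers blanketing S: occupied area = area(S), D = N / area(S)."""
        grid = self.big_grid()
        rng = np.random.default_rng(0)
        M = 400
        pts = grid.sample_uniform(rng, M)
        s = np.broadcast_to(pts.astype(np.float32), (1, 2, M, 2)).copy()
        post = fake_posterior([[M, M]], s=s, sigma=2.0)
        surf = density(post, grid, q=0.99, raster_km=0.2)
        assert surf.occupied_area_mean == pytest.approx(grid.total_area, rel=0.01)
        assert surf.d_mean == pytest.approx(M / grid.total_area, rel=0.01)

    def test_conservation_per_draw(self):
        """density x occupied area = N exactly, per draw, pre-rounding."""
        grid = self.big_grid()
        rng = np.random.default_rng(1)
        s = rng.uniform(5, 25, size=(1, 5, 20, 2)).astype(np.float32)
        z = (rng.random((1, 5, 20)) < 0.7).astype(np.uint8)
        z[..., 0] = 1
        post = fake_posterior([[20] * 5], s=s, z=z, sigma=0.8)
        surf = density(post, grid, raster_km=0.15)
        assert np.allclose(surf.d_draws * surf.area_draws, surf.N_draws)
        assert np.all(surf.N_draws == z.sum(axis=2)[0])

    def test_surface_integrates_to_mean_N(self):
        grid = self.big_grid()
        rng = np.random.default_rng(2)
        s = rng.uniform(2, 28, size=(2, 4, 30, 2)).astype(np.float32)
        z = (rng.random((2, 4, 30)) < 0.6).astype(np.uint8)
        z[..., 0] = 1
        Nd = z.sum(axis=2)
        post = fake_posterior(Nd, s=s, z=z, sigma=1.0)
        surf = density(post, grid, raster_km=0.25, max_draws=None)
        total = surf.cell_mean.sum() * grid.cell_area
        assert total == pytest.approx(Nd.mean(), rel=1e-9)

    def test_draw_without_individuals_skipped(self):
        grid = self.big_grid()
        s = np.full((1, 2, 3, 2), 15.0, dtype=np.float32)
        z = np.ones((1, 2, 3), np.uint8)
        z[0, 1] = 0
        post = fake_posterior([[3, 0]], s=s, z=z)
        with pytest.warns(UserWarning, match="no included individuals"):
            surf = density(post, grid, raster_km=0.3)
        assert surf.d_draws.size == 1


class TestTrend:
    def test_constant_series_is_stable(self):
        draws = np.full((500, 6), 250.0)
        t = trend(draws)
        assert t.stable and t.slope_mean == 0.0

    def test_doubling_series_excludes_zero(self):
        rng = np.random.default_rng(0)
        base = 100 * 2 ** np.arange(5)
        draws = rng.normal(base, 5, size=(1000, 5))
        t = trend(draws)
        assert not t.stable
        assert t.slope_ci[0] > 0

    def test_noisy_flat_series_contains_zero(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(300, 30, size=(1000, 9))
        assert trend(draws).stable

    def test_too_few_occasions(self):
        with pytest.raises(ValueError):
            trend(np.ones((100, 2)))


class TestInteractionFraction:
    def test_printed_ratio(self):
        post = fake_posterior([[8344] * 50])
        mean, ci, draws = interaction_fraction(1356, post)
        assert mean == pytest.approx(0.1625, abs=2e-4)

    def test_zero_observed(self):
        post = fake_posterior([[100] * 10])
        mean, ci, _ = interaction_fraction(0, post)
        assert mean == 0.0 and ci == (0.0, 0.0)

    def test_full_census(self):
        post = fake_posterior([[50] * 10])
        mean, _, _ = interaction_fraction(50, post)
        assert mean == 1.0

    def test_impossible_state(self):
        post = fake_posterior([[10, 5]])
        with pytest.raises(ValueError):
            interaction_fraction(8, post)


class TestTagRetention:
    def test_no_losses_upper_bound(self):
        tr = tag_retention(18, 18, 0.95)
        assert tr.loss_mle == 0.0
        assert tr.loss_upper == pytest.approx(0.1533, abs=2e-4)

    def test_all_lost(self):
        assert tag_retention(18, 0).loss_mle == 1.0

    def test_single_recapture(self):
        assert tag_retention(1, 1, 0.95).loss_upper == pytest.approx(0.95)

    def test_no_recaptures_rejected(self):
        with pytest.raises(ValueError):
            tag_retention(0, 0)

    def test_bound_consistent_with_binomial_tail(self):
        """The exact bound p_U satisfies P(X <= losses | n, p_U) = 1 - conf."""
        from scipy import stats

        tr = tag_retention(25, 22, 0.9)
        assert stats.binom.cdf(3, 25, tr.loss_upper) == pytest.approx(0.1, abs=1e-9)
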