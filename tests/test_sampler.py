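"""MCMC correctness: diagnostics, exact conditionals, determinism."""

import warnings

import numpy as np
import pytest

import gridscr
from gridscr.geometry import build_grid
from gridscr.data import EncounterData
from gridscr.sampler import (
    MCMCConfig,
    effective_sample_size,
    gelman_rubin,
    update_inclusion,
)

from conftest import make_recovery_dataset


class TestGelmanRubin:
    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 10_000))
        assert gelman_rubin(x) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 1000))
        x[1] += 10.0
        assert gelman_rubin(x) > 5.0

    def test_constant_chains_convention(self):
        assert gelman_rubin(np.ones((3, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        # mildly autocorrelated chains
        x = rng.normal(size=(4, 2000)).cumsum(axis=1) * 0.01 + rng.normal(
            size=(4, 2000)
        )
        ours = gelman_rubin(x)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(x))["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, rel=0.01)


class TestExactConditionals:
    def test_unreachable_individual_included_at_psi(self):
        """With zero expected hazard the inclusion conditional reduces to
        the prior psi."""
        rng = np.random.default_rng(0)
        z = update_inclusion(np.zeros(200_000), psi=0.37, rng=rng)
        assert z.mean() == pytest.approx(0.37, abs=0.005)

    def test_psi_zero_excludes_everyone(self):
        rng = np.random.default_rng(0)
        z = update_inclusion(np.zeros(1000), psi=1e-12, rng=rng)
        assert z.sum() == 0

    def test_bayes_rule_tiny_instance(self):
        """One cell, one occasion, p = 0.5, psi = 0.5:
        P(z=1 | y=0) = 0.5*0.5 / (0.5*0.5 + 0.5) = 1/3."""
        E = -np.log(1 - 0.5)  # hazard giving p = 0.5
        rng = np.random.default_rng(1)
        z = update_inclusion(np.full(300_000, E), psi=0.5, rng=rng)
        assert z.mean() == pytest.approx(1 / 3, abs=0.005)


class TestSamplerRuns:
    def test_identical_seeds_identical_chains(self):
        grid, cfg, pop, data, truth = make_recovery_dataset(
            3, N_true=60, K=3, grid=build_grid(
                centers=np.array([[1.0, 1.0], [3.0, 1.0], [1.0, 3.0], [3.0, 3.0]]),
                cell_size=2.0,
            )
        )
        model = gridscr.SCRModel(data, grid, effects=("effort",), sex_sigma=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = model.fit(n_iter=400, n_burn=100, n_chains=2, M=150, seed=9)
            r2 = model.fit(n_iter=400, n_burn=100, n_chains=2, M=150, seed=9)
            r3 = model.fit(n_iter=400, n_burn=100, n_chains=2, M=150, seed=10)
        for name in r1.post.params:
            assert np.array_equal(r1.post.params[name], r2.post.params[name])
        assert np.array_equal(r1.post.N, r2.post.N)
        assert np.array_equal(r1.post.s, r2.post.s)
        assert not np.array_equal(r3.post.N, r1.post.N)

    def test_psi_marginal_with_flat_likelihood(self):
        """With the baseline hazard pinned to ~0 every unobserved individual's
        likelihood is flat, so integrating z out leaves
        psi | data ~ Beta(n_obs + 1, 1)."""
        grid = build_grid(centers=np.array([[1.0, 1.0]]), cell_size=2.0)
        n_obs = 3
        y = np.zeros((n_obs, 1, 2), np.uint8)
        y[:, 0, 0] = 1
        data = EncounterData(
            y=y,
            effort=np.array([[1.0, 1.0]]),
            sex=np.zeros(n_obs, np.int8),
            size=np.full(n_obs, np.nan),
        )
        model = gridscr.SCRModel(data, grid, effects=(), sex_sigma=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(
                n_iter=30_000,
                n_burn=2000,
                n_chains=2,
                M=10,
                seed=4,
                fixed_params={"log_lambda0": -25.0, "log_sigma0": 0.0},
            )
        psi = res.post.draws("psi")
        a, b = n_obs + 1, 1.0
        assert psi.mean() == pytest.approx(a / (a + b), abs=0.01)
        assert psi.var() == pytest.approx(a * b / ((a + b) ** 2 * (a + b + 1)), abs=0.005)

    def test_augmented_centers_uniform_over_state_space(self):
        """Included-at-prior augmented individuals carry Uniform(S) activity
        centers: the per-cell histogram of stored centers is flat."""
        grid = build_grid(
            centers=np.array(
                [[1.0, 1.0], [3.0, 1.0], [1.0, 3.0], [3.0, 3.0], [5.0, 1.0], [5.0, 3.0]]
            ),
            cell_size=2.0,
        )
        y = np.zeros((1, 6, 1), np.uint8)
        y[0, 0, 0] = 1
        data = EncounterData(
            y=y,
            effort=np.ones((6, 1)),
            sex=np.array([0], np.int8),
            size=np.array([np.nan]),
        )
        model = gridscr.SCRModel(data, grid, effects=(), sex_sigma=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(
                MCMCConfig(
                    n_iter=6000, n_burn=1000, n_chains=2, M=60, seed=7, s_thin=1
                ),
                fixed_params={"log_lambda0": -25.0, "log_sigma0": 0.0},
            )
        s = res.post.s[:, :, 1:, :].reshape(-1, 2)  # augmented individuals only
        cells = grid.assign(s[:, 0], s[:, 1])
        counts = np.bincount(cells, minlength=6)
        from scipy import stats

        # draws are autocorrelated across iterations, so test cell
        # proportions with a generous tolerance rather than exact chi-square
        props = counts / counts.sum()
        assert np.all(np.abs(props - 1 / 6) < 0.02)
        assert stats.chisquare(counts).pvalue > 1e-6 or np.ptp(props) < 0.02

    def test_observed_individuals_never_excluded(self, small_fit):
        post = small_fit["results"].post
        assert np.all(post.z[:, :, : post.n_obs] == 1)
        assert np.all(post.N <= post.M)

    def test_augmentation_exhaustion_warns(self):
        grid, cfg, pop, data, truth = make_recovery_dataset(8, N_true=150, K=4)
        model = gridscr.SCRModel(data, grid, effects=("effort",), sex_sigma=False)
        with pytest.warns(UserWarning, match="increase the augmented size"):
            model.fit(n_iter=600, n_burn=200, n_chains=2, M=data.n_individuals + 3, seed=0)

    def test_acceptance_rates_in_target_band(self, small_fit):
        """Adaptation during burn-in should leave random-walk acceptance
        near the 0.3 target."""
        for rates in small_fit["results"].post.accept_rates:
            for name in ("activity_center", "log_lambda0", "log_sigma0", "beta_effort"):
                assert 0.1 < rates[name] < 0.6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burn=100)
        with pytest.warns(UserWarning, match="at least 2 chains"):
            MCMCConfig(n_chains=1)


class TestESS:
    def test_iid_ess_near_sample_size(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 5000))
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.15)

    def test_autocorrelated_ess_much_smaller(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = np.zeros((2, n))
        for c in range(2):
            for t in range(1, n):
                x[c, t] = 0.95 * x[c, t - 1] + rng.normal()
        assert effective_sample_size(x) < 2000
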