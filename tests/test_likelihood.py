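"""Hazard model, encounter probability, standardization and the
complete-data likelihood (checked against an independent triple-loop)."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gridscr
from gridscr.geometry import build_grid
from gridscr.likelihood import (
    AugmentedState,
    SCRParams,
    complete_data_loglik,
    encounter_prob,
    hazard_rate,
    standardize_covariates,
)


def loglik_triple_loop(data, state, params, grid, scaling, include_aug_priors=False):
    """Independent scalar-arithmetic evaluation of the complete-data
    log likelihood (the oracle for the vectorized implementation)."""
    total = 0.0
    n_obs = data.y.shape[0]
    for i in range(state.M):
        if state.z[i] == 0:
            continue
        sig = math.exp(params.log_sigma0 + params.beta_sigma_sex * state.sex[i])
        for j in range(data.n_cells):
            d2 = (state.s[i, 0] - grid.cell_centers[j, 0]) ** 2 + (
                state.s[i, 1] - grid.cell_centers[j, 1]
            ) ** 2
            for k in range(data.n_occasions):
                if data.effort[j, k] <= 0:
                    continue
                lam = math.exp(
                    params.log_lambda0
                    + params.beta_effort * scaling.effort_std[j, k]
                    + params.beta_sex * state.sex[i]
                    + params.beta_size * state.size_std[i]
                    - d2 / (2 * sig**2)
                )
                p = 1 - math.exp(-lam)
                yv = data.y[i, j, k] if i < n_obs else 0
                total += math.log(p) if yv == 1 else math.log(1 - p)
    if include_aug_priors:
        nz = int(state.z.sum())
        total += nz * math.log(params.psi) + (state.M - nz) * math.log(1 - params.psi)
        for i in range(state.M):
            if state.z[i] == 1:
                total += math.log(
                    params.psi_sex if state.sex[i] == 1 else 1 - params.psi_sex
                )
    return total


def random_instance(rng, M=20, J=12, K=3):
    """Random small model instance with guaranteed-valid data."""
    grid = build_grid(
        centers=np.column_stack(
            [
                (np.arange(J) % 4) * 2.0 + 1.0,
                (np.arange(J) // 4) * 2.0 + 1.0,
            ]
        ),
        cell_size=2.0,
    )
    effort = np.where(rng.random((J, K)) < 0.7, rng.integers(1, 4, (J, K)), 0).astype(float)
    if not (effort > 0).any():
        effort[0, 0] = 1.0
    params = SCRParams(
        log_lambda0=rng.normal(-0.5, 0.5),
        beta_effort=rng.normal(0, 0.3),
        beta_sex=rng.normal(0, 0.3),
        beta_size=rng.normal(0, 0.3),
        log_sigma0=rng.normal(0, 0.3),
        beta_sigma_sex=rng.normal(0, 0.1),
        psi=rng.uniform(0.2, 0.8),
        psi_sex=rng.uniform(0.2, 0.8),
    )
    s = grid.sample_uniform(rng, M)
    sex = rng.integers(0, 2, M).astype(np.int8)
    size_std = rng.normal(0, 1, M)
    z = np.ones(M, np.int8)
    n_obs = M // 2
    z[n_obs:] = rng.integers(0, 2, M - n_obs)
    # draw y from the model itself for the observed block; enforce >=1 capture
    d2 = ((s[:n_obs, None, :] - grid.cell_centers[None, :, :]) ** 2).sum(-1)
    sig = np.exp(params.log_sigma0 + params.beta_sigma_sex * sex[:n_obs])
    scal = standardize_covariates(effort, np.full(n_obs, np.nan))
    lam = np.exp(
        params.log_lambda0
        + params.beta_sex * sex[:n_obs, None, None]
        + params.beta_size * size_std[:n_obs, None, None]
        - d2[:, :, None] / (2 * sig[:n_obs, None, None] ** 2)
        + params.beta_effort * scal.effort_std[None, :, :]
    )
    y = ((rng.random(lam.shape) < 1 - np.exp(-lam)) & (effort[None] > 0)).astype(np.uint8)
    for i in range(n_obs):  # guarantee every observed row has an encounter
        if y[i].sum() == 0:
            jj, kk = np.nonzero(effort > 0)
            # nearest fished cell, so the encounter probability is not
            # vanishingly small
            t = np.argmin(d2[i, jj])
            y[i, jj[t], kk[t]] = 1
    data = gridscr.EncounterData(
        y=y, effort=effort, sex=sex[:n_obs], size=np.full(n_obs, np.nan)
    )
    state = AugmentedState(s=s, z=z, sex=sex, size_std=size_std)
    return data, state, params, grid, scal


class TestHazard:
    def test_baseline_at_zero_distance(self):
        p = SCRParams(log_lambda0=np.log(0.5))
        assert hazard_rate(0.0, p) == pytest.approx(0.5)

    def test_half_rate_distance(self):
        p = SCRParams(log_lambda0=np.log(0.5), log_sigma0=np.log(1.3))
        d = 1.3 * np.sqrt(2 * np.log(2))
        assert hazard_rate(d, p) == pytest.approx(0.25)

    def test_direct_evaluation(self):
        p = SCRParams(log_lambda0=np.log(0.5), log_sigma0=0.0)
        assert hazard_rate(1.0, p) == pytest.approx(0.30327, abs=1e-5)

    def test_strictly_decreasing_in_distance(self):
        p = SCRParams(log_lambda0=0.3, log_sigma0=np.log(0.8))
        d = np.linspace(0, 10, 200)
        lam = hazard_rate(d, p)
        assert np.all(np.diff(lam) < 0)

    def test_increasing_in_effort_with_positive_slope(self):
        p = SCRParams(beta_effort=0.5)
        e = np.linspace(-2, 2, 50)
        lam = hazard_rate(1.0, p, effort_std=e)
        assert np.all(np.diff(lam) > 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            hazard_rate(-0.1, SCRParams())


class TestEncounterProb:
    @pytest.mark.parametrize(
        "lam,expected", [(0.0, 0.0), (np.log(2), 0.5), (0.30327, 0.26161)]
    )
    def test_closed_form_values(self, lam, expected):
        assert encounter_prob(lam) == pytest.approx(expected, abs=1e-5)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            encounter_prob(-1e-9)

    @given(st.floats(0, 30), st.floats(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        pa, pb = encounter_prob(a), encounter_prob(b)
        assert 0 <= pa < 1
        if a < b:
            assert pa <= pb


class TestStandardize:
    def test_equal_effort_centers_to_zero(self):
        eff = np.full((3, 2), 2.0)
        with pytest.warns(UserWarning, match="zero variance"):
            sc = standardize_covariates(eff, np.array([100.0, 120.0]))
        assert np.all(sc.effort_std == 0.0)
        assert sc.effort_degenerate

    def test_two_effort_values_sample_sd(self):
        eff = np.array([[1.0], [3.0]])
        sc = standardize_covariates(eff, np.array([np.nan]))
        assert sc.effort_std[:, 0] == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_sizes_z_scored_with_sample_sd(self):
        eff = np.array([[1.0, 2.0]])
        sc = standardize_covariates(eff, np.array([100.0, 120.0, 140.0]))
        assert sc.size_sd == pytest.approx(20.0)
        assert sc.size_std == pytest.approx([-1.0, 0.0, 1.0])

    def test_unsampled_slots_excluded_from_stats(self):
        eff = np.array([[0.0, 1.0], [3.0, 0.0]])
        sc = standardize_covariates(eff, np.array([np.nan]))
        assert sc.effort_mean == pytest.approx(2.0)
        assert sc.effort_std[0, 0] == 0.0  # unsampled slot untouched

    def test_all_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            standardize_covariates(np.zeros((2, 2)), np.array([np.nan]))


class TestCompleteDataLoglik:
    def _one_cell_setup(self, y_val):
        grid = build_grid(centers=np.array([[1.0, 1.0]]), cell_size=2.0)
        y = np.array([[[y_val]]], dtype=np.uint8)
        effort = np.array([[1.0]])
        if y_val == 0:
            # an all-zero observed row is invalid data; use an augmented row
            data = gridscr.EncounterData(
                y=np.zeros((0, 1, 1), np.uint8),
                effort=effort,
                sex=np.zeros(0, np.int8),
                size=np.zeros(0),
            )
            state = AugmentedState(
                s=np.array([[1.0, 1.0]]), z=[1], sex=[0], size_std=[0.0]
            )
        else:
            data = gridscr.EncounterData(
                y=y, effort=effort, sex=np.array([0], np.int8), size=np.array([np.nan])
            )
            state = AugmentedState(
                s=np.array([[1.0, 1.0]]), z=[1], sex=[0], size_std=[0.0]
            )
        params = SCRParams(log_lambda0=np.log(np.log(2)))  # lambda = ln 2 -> p = 0.5
        return data, state, params, grid

    def test_single_encounter_at_half_probability(self):
        data, state, params, grid = self._one_cell_setup(1)
        ll = complete_data_loglik(data, state, params, grid)
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_single_nonencounter_symmetric_at_half(self):
        data, state, params, grid = self._one_cell_setup(0)
        ll = complete_data_loglik(data, state, params, grid)
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data, state, params, grid, scal = random_instance(rng)
            v = complete_data_loglik(data, state, params, grid, scaling=scal)
            o = loglik_triple_loop(data, state, params, grid, scal)
            assert v == pytest.approx(o, abs=1e-10)

    def test_augmentation_prior_terms(self):
        rng = np.random.default_rng(3)
        data, state, params, grid, scal = random_instance(rng, M=10, J=4, K=2)
        v = complete_data_loglik(
            data, state, params, grid, scaling=scal, include_aug_priors=True
        )
        o = loglik_triple_loop(data, state, params, grid, scal, include_aug_priors=True)
        assert v == pytest.approx(o, abs=1e-10)

    def test_invariant_to_permuting_augmented_rows(self):
        rng = np.random.default_rng(5)
        data, state, params, grid, scal = random_instance(rng)
        n_obs = data.n_individuals
        v1 = complete_data_loglik(data, state, params, grid, scaling=scal)
        perm = n_obs + rng.permutation(state.M - n_obs)
        state2 = AugmentedState(
            s=np.concatenate([state.s[:n_obs], state.s[perm]]),
            z=np.concatenate([state.z[:n_obs], state.z[perm]]),
            sex=np.concatenate([state.sex[:n_obs], state.sex[perm]]),
            size_std=np.concatenate([state.size_std[:n_obs], state.size_std[perm]]),
        )
        v2 = complete_data_loglik(data, state2, params, grid, scaling=scal)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_impossible_encounter_in_unfished_cell(self):
        grid = build_grid(centers=np.array([[1.0, 1.0], [3.0, 1.0]]), cell_size=2.0)
        effort = np.array([[1.0], [0.0]])
        y = np.zeros((1, 2, 1), np.uint8)
        y[0, 0, 0] = 1
        data = gridscr.EncounterData(
            y=y, effort=effort, sex=np.array([0], np.int8), size=np.array([np.nan])
        )
        state = AugmentedState(s=np.array([[1.0, 1.0]]), z=[1], sex=[0], size_std=[0.0])
        # bypass EncounterData validation by editing y after construction
        data.y[0, 1, 0] = 1
        with pytest.warns(UserWarning, match="zero-effort"):
            ll = complete_data_loglik(data, state, SCRParams(), grid)
        assert ll == -np.inf

    def test_zero_effort_slots_contribute_nothing(self):
        """Doubling y's occasions with unfished slots leaves the likelihood
        unchanged: p = 0 exactly where effort = 0."""
        rng = np.random.default_rng(9)
        data, state, params, grid, scal = random_instance(rng, M=8, J=4, K=2)
        y2 = np.concatenate([data.y, np.zeros_like(data.y)], axis=2)
        eff2 = np.concatenate([data.effort, np.zeros_like(data.effort)], axis=1)
        data2 = gridscr.EncounterData(y=y2, effort=eff2, sex=data.sex, size=data.size)
        scal2 = standardize_covariates(eff2, data.size)
        v1 = complete_data_loglik(data, state, params, grid, scaling=scal)
        v2 = complete_data_loglik(data2, state, params, grid, scaling=scal2)
        assert v1 == pytest.approx(v2, abs=1e-10)
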