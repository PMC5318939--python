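"""Numba core of the Metropolis-within-Gibbs sampler.

One jitted function runs one chain.  The expensive quantity is, per
individual, the total expected hazard over all sampled cell-occasions,

    E_i = c_i * sum_j exp(-d_ij^2 / (2 sigma_i^2)) * H_j,
    H_j = sum_k 1[effort_jk > 0] * exp(beta_eff * effort_std_jk),

because the all-zero part of each encounter history contributes exactly -E_i
to the log likelihood.  The (sparse) observed encounters add
log(1 - exp(-lam)) + lam per y = 1 entry.  E_i, the per-one hazards and the
per-individual log-likelihood contribution are cached and updated
incrementally: proposals that only rescale the hazard (log lambda0, sex and
size slopes, latent sizes) cost O(M + ones), while proposals that change the
kernel or effort weights (sigma parameters, effort slope) and the
activity-center sweep cost one O(M x J) pass.

Parameter order in vectors: [log_lambda0, beta_effort, beta_sex, beta_size,
log_sigma0, beta_sigma_sex]; psi and psi_sex are Gibbs-updated separately.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# proposal/acceptance slots
N_PROP = 8  # s, ll0, beff, bsex, bsize, lsig0, bsigsex, latent size

# hard numerical bounds on log-scale proposals (well outside any posterior mass)
_LL0_LO, _LL0_HI = -30.0, 10.0
_BETA_BOUND = 20.0


@njit(cache=True, inline="always")
def _log1mexp(lam):
    """log(1 - exp(-lam)) for lam >= 0."""
    if lam <= 0.0:
        return -1e300
    if lam < 1e-10:
        return math.log(lam)
    return math.log(-math.expm1(-lam))


@njit(cache=True, inline="always")
def _in_state_space(x, y, x0, y0, cs, nx, ny, lat2act):
    ix = int(math.floor((x - x0) / cs))
    iy = int(math.floor((y - y0) / cs))
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
        return False
    return lat2act[iy * nx + ix] >= 0


@njit(cache=True)
def _effort_terms(beff, eff_std, sampled, ones_cell, ones_occ, H, heff):
    J, K = eff_std.shape
    for j in range(J):
        h = 0.0
        for k in range(K):
            if sampled[j, k]:
                h += math.exp(beff * eff_std[j, k])
        H[j] = h
    for t in range(ones_cell.shape[0]):
        heff[t] = math.exp(beff * eff_std[ones_cell[t], ones_occ[t]])


@njit(cache=True)
def _el_i(i, sxi, syi, sexi, sizei, p, cellx, celly, H, heff,
          ones_ptr, ones_cell, ones_occ, n_obs, lam_out):
    """E_i and sum of one-terms for individual i; writes per-one hazards
    into lam_out at i's slots."""
    sig = math.exp(p[4] + p[5] * sexi)
    inv = 1.0 / (2.0 * sig * sig)
    c = math.exp(p[0] + p[2] * sexi + p[3] * sizei)
    G = 0.0
    J = cellx.shape[0]
    for j in range(J):
        dx = sxi - cellx[j]
        dy = syi - celly[j]
        G += math.exp(-(dx * dx + dy * dy) * inv) * H[j]
    E = c * G
    Lon = 0.0
    if i < n_obs:
        for t in range(ones_ptr[i], ones_ptr[i + 1]):
            j = ones_cell[t]
            dx = sxi - cellx[j]
            dy = syi - celly[j]
            lam = c * math.exp(-(dx * dx + dy * dy) * inv) * heff[t]
            lam_out[t] = lam
            Lon += _log1mexp(lam) + lam
    return E, Lon


@njit(cache=True)
def _full_pass(p, sx, sy, sexc, sizec, cellx, celly, H, heff,
               ones_ptr, ones_cell, ones_occ, n_obs, E, Lon, lamones):
    M = sx.shape[0]
    for i in range(M):
        E[i], Lon[i] = _el_i(i, sx[i], sy[i], sexc[i], sizec[i], p,
                             cellx, celly, H, heff,
                             ones_ptr, ones_cell, ones_occ, n_obs, lamones)


@njit(cache=True)
def run_chain(
    seed,
    n_iter, n_burn, thin, s_every,
    M, n_obs,
    cellx, celly,
    x0, y0, cs, nx, ny, lat2act,
    eff_std, sampled,
    ones_ptr, ones_cell, ones_occ,
    sex_obs, size_obs,
    use_eff, use_sex, use_size, use_sigsex,
    size_lo, size_hi,
    prior_mu_ll0, prior_sd_ll0, prior_sd_beta, sigma_lo, sigma_hi,
    init_params, init_psi, init_psisex,
    init_sx, init_sy, init_z, init_sex, init_size,
    steps0,
    adapt_every,
):
    """Run one MCMC chain; returns kept draws and diagnostics.

    Returns (params_out [n_keep, 8], N_out [n_keep], sx_out, sy_out, z_out,
    sex_out [n_keep_s, M], accept_rates [N_PROP], adapted step sizes).
    """
    np.random.seed(seed)
    J = cellx.shape[0]
    n_ones = ones_cell.shape[0]

    # mutable state
    p = init_params.copy()
    psi = init_psi
    psisex = init_psisex
    sx = init_sx.copy()
    sy = init_sy.copy()
    z = init_z.copy()
    sexc = init_sex.copy()
    sizec = init_size.copy()
    steps = steps0.copy()

    H = np.zeros(J)
    heff = np.zeros(n_ones)
    _effort_terms(p[1], eff_std, sampled, ones_cell, ones_occ, H, heff)
    H_prop = np.zeros(J)
    heff_prop = np.zeros(n_ones)

    E = np.zeros(M)
    Lon = np.zeros(M)
    lamones = np.zeros(n_ones)
    E_prop = np.zeros(M)
    Lon_prop = np.zeros(M)
    lamones_prop = np.zeros(n_ones)
    _full_pass(p, sx, sy, sexc, sizec, cellx, celly, H, heff,
               ones_ptr, ones_cell, ones_occ, n_obs, E, Lon, lamones)

    n_keep = (n_iter - n_burn + thin - 1) // thin
    n_keep_s = (n_keep + s_every - 1) // s_every
    params_out = np.zeros((n_keep, 8))
    N_out = np.zeros(n_keep, dtype=np.int64)
    sx_out = np.zeros((n_keep_s, M))
    sy_out = np.zeros((n_keep_s, M))
    z_out = np.zeros((n_keep_s, M), dtype=np.uint8)
    sex_out = np.zeros((n_keep_s, M), dtype=np.uint8)

    acc = np.zeros(N_PROP)
    tries = np.zeros(N_PROP)
    acc_win = np.zeros(N_PROP)
    tries_win = np.zeros(N_PROP)
    win_count = 0

    inv_2sd2_ll0 = 1.0 / (2.0 * prior_sd_ll0 * prior_sd_ll0)
    inv_2sd2_beta = 1.0 / (2.0 * prior_sd_beta * prior_sd_beta)

    keep_idx = 0
    for it in range(n_iter):
        # ---- scaling parameter updates: ll0 (0), bsex (2), bsize (3) ----
        for pidx in (0, 2, 3):
            if pidx == 2 and use_sex == 0:
                continue
            if pidx == 3 and use_size == 0:
                continue
            sl = pidx + 1  # proposal slot (slot 0 is the activity-center move)
            if steps[sl] <= 0.0:
                continue  # pinned parameter
            d = np.random.normal() * steps[sl]
            new = p[pidx] + d
            if pidx == 0:
                if new < _LL0_LO or new > _LL0_HI:
                    tries[sl] += 1.0
                    tries_win[sl] += 1.0
                    continue
                dprior = ((p[0] - prior_mu_ll0) ** 2 - (new - prior_mu_ll0) ** 2) * inv_2sd2_ll0
            else:
                if abs(new) > _BETA_BOUND:
                    tries[sl] += 1.0
                    tries_win[sl] += 1.0
                    continue
                dprior = (p[pidx] ** 2 - new ** 2) * inv_2sd2_beta
            dll = 0.0
            for i in range(M):
                if z[i] == 0:
                    continue
                if pidx == 0:
                    x_i = 1.0
                elif pidx == 2:
                    x_i = sexc[i]
                else:
                    x_i = sizec[i]
                f = math.exp(d * x_i)
                Ep = E[i] * f
                Lonp = 0.0
                if i < n_obs:
                    for t in range(ones_ptr[i], ones_ptr[i + 1]):
                        lam = lamones[t] * f
                        Lonp += _log1mexp(lam) + lam
                dll += (Lonp - Ep) - (Lon[i] - E[i])
            tries[sl] += 1.0
            tries_win[sl] += 1.0
            if math.log(np.random.random()) < dll + dprior:
                acc[sl] += 1.0
                acc_win[sl] += 1.0
                p[pidx] = new
                for i in range(M):
                    if pidx == 0:
                        x_i = 1.0
                    elif pidx == 2:
                        x_i = sexc[i]
                    else:
                        x_i = sizec[i]
                    f = math.exp(d * x_i)
                    E[i] = E[i] * f
                    if i < n_obs:
                        Lonp = 0.0
                        for t in range(ones_ptr[i], ones_ptr[i + 1]):
                            lamones[t] = lamones[t] * f
                            Lonp += _log1mexp(lamones[t]) + lamones[t]
                        Lon[i] = Lonp

        # ---- kernel/effort parameter updates: beff (1), lsig0 (4), bsigsex (5) ----
        for pidx in (1, 4, 5):
            if pidx == 1 and use_eff == 0:
                continue
            if pidx == 5 and use_sigsex == 0:
                continue
            sl = pidx + 1
            if steps[sl] <= 0.0:
                continue  # pinned parameter
            d = np.random.normal() * steps[sl]
            new = p[pidx] + d
            tries[sl] += 1.0
            tries_win[sl] += 1.0
            if pidx == 4:
                sig0 = math.exp(new)
                if sig0 < sigma_lo or sig0 > sigma_hi:
                    continue
                # sigma0 ~ Uniform => density on log sigma0 carries Jacobian sigma0
                dprior = new - p[4]
            else:
                if abs(new) > _BETA_BOUND:
                    continue
                dprior = (p[pidx] ** 2 - new ** 2) * inv_2sd2_beta
            pp = p.copy()
            pp[pidx] = new
            if pidx == 1:
                _effort_terms(new, eff_std, sampled, ones_cell, ones_occ, H_prop, heff_prop)
                _full_pass(pp, sx, sy, sexc, sizec, cellx, celly, H_prop, heff_prop,
                           ones_ptr, ones_cell, ones_occ, n_obs, E_prop, Lon_prop, lamones_prop)
            else:
                _full_pass(pp, sx, sy, sexc, sizec, cellx, celly, H, heff,
                           ones_ptr, ones_cell, ones_occ, n_obs, E_prop, Lon_prop, lamones_prop)
            dll = 0.0
            for i in range(M):
                if z[i] == 1:
                    dll += (Lon_prop[i] - E_prop[i]) - (Lon[i] - E[i])
            if math.log(np.random.random()) < dll + dprior:
                acc[sl] += 1.0
                acc_win[sl] += 1.0
                p[pidx] = new
                E, E_prop = E_prop, E
                Lon, Lon_prop = Lon_prop, Lon
                lamones, lamones_prop = lamones_prop, lamones
                if pidx == 1:
                    H, H_prop = H_prop, H
                    heff, heff_prop = heff_prop, heff

        # ---- latent sex ----
        sex_in_lik = (use_sex != 0) or (use_sigsex != 0)
        for i in range(M):
            if sex_obs[i] >= 0:
                continue
            if z[i] == 0:
                sexc[i] = 1.0 if np.random.random() < psisex else 0.0
            elif not sex_in_lik:
                sexc[i] = 1.0 if np.random.random() < psisex else 0.0
            else:
                E1, L1 = _el_i(i, sx[i], sy[i], 1.0, sizec[i], p, cellx, celly,
                               H, heff, ones_ptr, ones_cell, ones_occ, n_obs, lamones_prop)
                E0, L0 = _el_i(i, sx[i], sy[i], 0.0, sizec[i], p, cellx, celly,
                               H, heff, ones_ptr, ones_cell, ones_occ, n_obs, lamones_prop)
                lw1 = math.log(psisex) + L1 - E1
                lw0 = math.log(1.0 - psisex) + L0 - E0
                p1 = 1.0 / (1.0 + math.exp(lw0 - lw1))
                male = np.random.random() < p1
                newsex = 1.0 if male else 0.0
                if newsex != sexc[i]:
                    sexc[i] = newsex
                    E[i], Lon[i] = _el_i(i, sx[i], sy[i], newsex, sizec[i], p,
                                         cellx, celly, H, heff,
                                         ones_ptr, ones_cell, ones_occ, n_obs, lamones)

        # ---- latent size (standardized scale, N(0,1) truncated prior) ----
        if use_size != 0:
            for i in range(M):
                if np.isfinite(size_obs[i]):
                    continue
                if z[i] == 0:
                    # direct truncated-normal prior draw (rejection; bounds are
                    # the observed range, so acceptance is high)
                    for _ in range(200):
                        v = np.random.normal()
                        if size_lo <= v <= size_hi:
                            sizec[i] = v
                            break
                    E[i], Lon[i] = _el_i(i, sx[i], sy[i], sexc[i], sizec[i], p,
                                         cellx, celly, H, heff,
                                         ones_ptr, ones_cell, ones_occ, n_obs, lamones)
                else:
                    prop = sizec[i] + np.random.normal() * steps[7]
                    tries[7] += 1.0
                    tries_win[7] += 1.0
                    if prop < size_lo or prop > size_hi:
                        continue
                    f = math.exp(p[3] * (prop - sizec[i]))
                    Ep = E[i] * f
                    Lonp = 0.0
                    if i < n_obs:
                        for t in range(ones_ptr[i], ones_ptr[i + 1]):
                            lam = lamones[t] * f
                            Lonp += _log1mexp(lam) + lam
                    dll = (Lonp - Ep) - (Lon[i] - E[i])
                    dprior = 0.5 * (sizec[i] ** 2 - prop ** 2)
                    if math.log(np.random.random()) < dll + dprior:
                        acc[7] += 1.0
                        acc_win[7] += 1.0
                        sizec[i] = prop
                        E[i] = Ep
                        Lon[i] = Lonp
                        if i < n_obs:
                            for t in range(ones_ptr[i], ones_ptr[i + 1]):
                                lamones[t] = lamones[t] * f

        # ---- activity centers ----
        for i in range(M):
            if z[i] == 0 and i >= n_obs:
                j = np.random.randint(0, J)
                sx[i] = cellx[j] + (np.random.random() - 0.5) * cs
                sy[i] = celly[j] + (np.random.random() - 0.5) * cs
                E[i], Lon[i] = _el_i(i, sx[i], sy[i], sexc[i], sizec[i], p,
                                     cellx, celly, H, heff,
                                     ones_ptr, ones_cell, ones_occ, n_obs, lamones)
            else:
                px = sx[i] + np.random.normal() * steps[0]
                py = sy[i] + np.random.normal() * steps[0]
                tries[0] += 1.0
                tries_win[0] += 1.0
                if not _in_state_space(px, py, x0, y0, cs, nx, ny, lat2act):
                    continue
                Ep, Lonp = _el_i(i, px, py, sexc[i], sizec[i], p, cellx, celly,
                                 H, heff, ones_ptr, ones_cell, ones_occ, n_obs,
                                 lamones_prop)
                dll = (Lonp - Ep) - (Lon[i] - E[i])
                if math.log(np.random.random()) < dll:
                    acc[0] += 1.0
                    acc_win[0] += 1.0
                    sx[i] = px
                    sy[i] = py
                    E[i] = Ep
                    Lon[i] = Lonp
                    if i < n_obs:
                        for t in range(ones_ptr[i], ones_ptr[i + 1]):
                            lamones[t] = lamones_prop[t]

        # ---- inclusion indicators ----
        lo_psi = math.log(psi / (1.0 - psi))
        for i in range(n_obs, M):
            lodds = lo_psi - E[i]
            pz = 1.0 / (1.0 + math.exp(-lodds))
            z[i] = 1 if np.random.random() < pz else 0

        # ---- psi, psi_sex (conjugate Gibbs) ----
        nz = 0
        nm = 0
        for i in range(M):
            if z[i] == 1:
                nz += 1
                if sexc[i] > 0.5:
                    nm += 1
        psi = np.random.beta(1.0 + nz, 1.0 + M - nz)
        psisex = np.random.beta(1.0 + nm, 1.0 + nz - nm)

        # ---- adaptation (burn-in only; kernel frozen afterwards) ----
        if it < n_burn:
            if (it + 1) % adapt_every == 0:
                win_count += 1
                rm = 1.0 / math.sqrt(win_count)
                for a in range(N_PROP):
                    if tries_win[a] > 0:
                        rate = acc_win[a] / tries_win[a]
                        steps[a] = steps[a] * math.exp((rate - 0.3) * rm)
                    acc_win[a] = 0.0
                    tries_win[a] = 0.0
            if it == n_burn - 1:
                # acceptance bookkeeping restarts for the sampling phase
                for a in range(N_PROP):
                    acc[a] = 0.0
                    tries[a] = 0.0

        # ---- storage ----
        if it >= n_burn and (it - n_burn) % thin == 0:
            params_out[keep_idx, 0] = p[0]
            params_out[keep_idx, 1] = p[1]
            params_out[keep_idx, 2] = p[2]
            params_out[keep_idx, 3] = p[3]
            params_out[keep_idx, 4] = p[4]
            params_out[keep_idx, 5] = p[5]
            params_out[keep_idx, 6] = psi
            params_out[keep_idx, 7] = psisex
            N_out[keep_idx] = nz
            if keep_idx % s_every == 0:
                ks = keep_idx // s_every
                for i in range(M):
                    sx_out[ks, i] = sx[i]
                    sy_out[ks, i] = sy[i]
                    z_out[ks, i] = z[i]
                    sex_out[ks, i] = 1 if sexc[i] > 0.5 else 0
            keep_idx += 1

    rates = np.zeros(N_PROP)
    for a in range(N_PROP):
        if tries[a] > 0:
            rates[a] = acc[a] / tries[a]
    return params_out, N_out, sx_out, sy_out, z_out, sex_out, rates, steps
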