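"""Numba-compiled Metropolis-within-Gibbs kernels.

One chain per call; chains are looped (with distinct seeds and initial
values) by the wrappers in :mod:`ceeresponse.latent` and
:mod:`ceeresponse.dose_response`.  Each latent-state kernel iterates

* exact Gibbs draws of the per-block latent state z_t given (lambda, p),
* conjugate Beta draws of the phase probabilities p_phase given z,
* adaptive random-walk Metropolis for the log-link parameters targeting the
  z-marginalised conditional p(lambda | p, y) — the per-block likelihood is
  the two-term mixture over z, which factorises across blocks, so
  marginalising costs one pass over the data per proposal and removes the
  sticky coupling between z and lambda that traps z-conditioned updates in
  minor modes.

The scan (z -> p | z -> lambda | p) leaves the marginal posterior of
(lambda, p) invariant with z as a transient auxiliary variable; the z draw
is a valid posterior state draw and feeds the per-draw speed summaries of
the movement family.  Proposal scales are tuned toward a 0.44 acceptance
rate during burn-in only, then frozen so the kept draws come from a fixed
kernel.  Uniform priors are enforced by rejecting proposals outside their
bounds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LAM0_LO, LAM0_HI = -30.0, 30.0
LAM1_LO, LAM1_HI = 0.0, 30.0
SD_LO, SD_HI = 0.0, 30.0

FAMILY_POISSON = 0
FAMILY_TRUNC_NORMAL = 1

_ADAPT_WINDOW = 50
_TARGET_ACC = 0.44


@njit(cache=True)
def _log_phi(x):
    """log of the standard normal CDF, for x not extremely negative."""
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))


@njit(cache=True)
def _adapt(scale, acc, target=_TARGET_ACC):
    s = scale * math.exp(2.0 * (acc - target))
    if s < 1e-4:
        s = 1e-4
    if s > 50.0:
        s = 50.0
    return s


@njit(cache=True)
def _mix_ll(lf0, lf1, pz):
    """log of the two-component mixture (1-p) f0 + p f1 from log-densities."""
    if lf0 > lf1:
        return lf0 + math.log((1.0 - pz) + pz * math.exp(lf1 - lf0))
    return lf1 + math.log(pz + (1.0 - pz) * math.exp(lf0 - lf1))


@njit(cache=True)
def _counts_marginal_ll(y, obs, phase, p, family, lam0, lam1, sd):
    """z-marginalised log-likelihood of the observed blocks."""
    mu0 = math.exp(lam0)
    mu1 = math.exp(lam0 + lam1)
    l0c = 0.0
    l1c = 0.0
    if family == FAMILY_TRUNC_NORMAL:
        l0c = -math.log(sd) - _log_phi(mu0 / sd)
        l1c = -math.log(sd) - _log_phi(mu1 / sd)
    ll = 0.0
    for t in range(y.shape[0]):
        if not obs[t]:
            continue
        yt = y[t]
        if family == FAMILY_POISSON:
            # lgamma(y+1) is constant in the parameters and dropped
            lf0 = yt * lam0 - mu0
            lf1 = yt * (lam0 + lam1) - mu1
        else:
            r0 = (yt - mu0) / sd
            r1 = (yt - mu1) / sd
            lf0 = -0.5 * r0 * r0 + l0c
            lf1 = -0.5 * r1 * r1 + l1c
        ll += _mix_ll(lf0, lf1, p[phase[t]])
    return ll


@njit(cache=True)
def counts_chain(
    y,
    obs,
    phase,
    family,
    n_burn,
    n_keep,
    seed,
    lam0_init,
    lam1_init,
    sd_init,
):
    """One MCMC chain for the Poisson / truncated-normal latent-state model.

    Returns ``(lam0_draws, lam1_draws, sd_draws, p_draws, accept_rate)``
    with p_draws of shape (n_keep, 3).
    """
    np.random.seed(seed)
    T = y.shape[0]

    lam0 = lam0_init
    lam1 = lam1_init
    sd = sd_init
    p = np.random.random(3)

    lam0_d = np.empty(n_keep)
    lam1_d = np.empty(n_keep)
    sd_d = np.empty(n_keep)
    p_d = np.empty((n_keep, 3))

    scale0 = 0.5
    scale1 = 0.5
    scale_sd = 0.5
    acc0 = 0
    acc1 = 0
    acc_sd = 0
    n_prop = 0
    acc_total = 0.0
    prop_total = 0.0
    n_param = 3.0 if family == FAMILY_TRUNC_NORMAL else 2.0

    for it in range(n_burn + n_keep):
        # --- latent states (exact Gibbs given lambda, p)
        mu0 = math.exp(lam0)
        mu1 = math.exp(lam0 + lam1)
        lp1_const = 0.0
        lp0_const = 0.0
        if family == FAMILY_TRUNC_NORMAL:
            lp1_const = -_log_phi(mu1 / sd)
            lp0_const = -_log_phi(mu0 / sd)
        nz = np.zeros(3)
        ntot = np.zeros(3)
        for t in range(T):
            ph = phase[t]
            pz = p[ph]
            if obs[t]:
                yt = y[t]
                if family == FAMILY_POISSON:
                    dll = yt * lam1 - (mu1 - mu0)
                else:
                    r1 = (yt - mu1) / sd
                    r0 = (yt - mu0) / sd
                    dll = -0.5 * (r1 * r1 - r0 * r0) + lp1_const - lp0_const
                # P(z=1 | y, p) = pz f1 / (pz f1 + (1-pz) f0)
                if dll > 0.0:
                    q = pz / (pz + (1.0 - pz) * math.exp(-dll))
                else:
                    q = pz * math.exp(dll) / (pz * math.exp(dll) + 1.0 - pz)
                zt = 1 if np.random.random() < q else 0
            else:
                zt = 1 if np.random.random() < pz else 0
            ntot[ph] += 1.0
            nz[ph] += zt

        # --- phase probabilities (conjugate Beta given z)
        for ph in range(3):
            p[ph] = np.random.beta(1.0 + nz[ph], 1.0 + ntot[ph] - nz[ph])

        # --- log-link parameters (random-walk MH on the z-marginal target)
        cur = _counts_marginal_ll(y, obs, phase, p, family, lam0, lam1, sd)
        n_prop += 1
        prop_total += n_param

        cand = lam0 + scale0 * np.random.normal()
        if LAM0_LO < cand < LAM0_HI:
            new = _counts_marginal_ll(y, obs, phase, p, family, cand, lam1, sd)
            if math.log(np.random.random()) < new - cur:
                lam0 = cand
                cur = new
                acc0 += 1
                acc_total += 1.0

        cand = lam1 + scale1 * np.random.normal()
        if LAM1_LO <= cand < LAM1_HI:
            new = _counts_marginal_ll(y, obs, phase, p, family, lam0, cand, sd)
            if math.log(np.random.random()) < new - cur:
                lam1 = cand
                cur = new
                acc1 += 1
                acc_total += 1.0

        if family == FAMILY_TRUNC_NORMAL:
            cand = sd + scale_sd * np.random.normal()
            if SD_LO < cand < SD_HI:
                new = _counts_marginal_ll(
                    y, obs, phase, p, family, lam0, lam1, cand
                )
                if math.log(np.random.random()) < new - cur:
                    sd = cand
                    acc_sd += 1
                    acc_total += 1.0

        if it < n_burn and n_prop == _ADAPT_WINDOW:
            scale0 = _adapt(scale0, acc0 / _ADAPT_WINDOW)
            scale1 = _adapt(scale1, acc1 / _ADAPT_WINDOW)
            scale_sd = _adapt(scale_sd, acc_sd / _ADAPT_WINDOW)
            acc0 = 0
            acc1 = 0
            acc_sd = 0
            n_prop = 0

        if it >= n_burn:
            k = it - n_burn
            lam0_d[k] = lam0
            lam1_d[k] = lam1
            sd_d[k] = sd
            p_d[k, 0] = p[0]
            p_d[k, 1] = p[1]
            p_d[k, 2] = p[2]

    return lam0_d, lam1_d, sd_d, p_d, acc_total / prop_total


@njit(cache=True)
def _movement_regimes(l0b, l1b, l0s, l1s, delta, rho, var_ar, var_st, lv_ar, lv_st):
    for zv in range(2):
        beta = math.exp(l0b + l1b * zv)
        sig = math.exp(l0s + l1s * zv)
        r = math.exp(-beta * delta)
        tau2 = sig * sig / (2.0 * beta)
        rho[zv] = r
        var_st[zv] = tau2
        var_ar[zv] = tau2 * (1.0 - r * r)
        lv_st[zv] = math.log(tau2)
        lv_ar[zv] = math.log(var_ar[zv])


@njit(cache=True, inline="always")
def _movement_block_lf(vx, vy, ttype, t, zv, rho, var_ar, var_st, lv_ar, lv_st):
    """Log-density of block t's velocity under state zv (ttype[t] != 0),
    up to the -log(2 pi) constant shared by both states."""
    if ttype[t] == 2:
        d1 = vx[t] - rho[zv] * vx[t - 1]
        d2 = vy[t] - rho[zv] * vy[t - 1]
        return -(d1 * d1 + d2 * d2) / (2.0 * var_ar[zv]) - lv_ar[zv]
    d1 = vx[t]
    d2 = vy[t]
    return -(d1 * d1 + d2 * d2) / (2.0 * var_st[zv]) - lv_st[zv]


@njit(cache=True)
def _movement_marginal_ll(vx, vy, ttype, phase, p, l0b, l1b, l0s, l1s, delta):
    """z-marginalised OU block-velocity log-likelihood (up to a constant).

    Each block's transition density depends only on its own state (the
    previous velocity is data), so the mixture factorises across blocks.
    """
    rho = np.empty(2)
    var_ar = np.empty(2)
    var_st = np.empty(2)
    lv_ar = np.empty(2)
    lv_st = np.empty(2)
    _movement_regimes(l0b, l1b, l0s, l1s, delta, rho, var_ar, var_st, lv_ar, lv_st)
    ll = 0.0
    for t in range(vx.shape[0]):
        if ttype[t] == 0:
            continue
        lf0 = _movement_block_lf(vx, vy, ttype, t, 0, rho, var_ar, var_st, lv_ar, lv_st)
        lf1 = _movement_block_lf(vx, vy, ttype, t, 1, rho, var_ar, var_st, lv_ar, lv_st)
        ll += _mix_ll(lf0, lf1, p[phase[t]])
    return ll


@njit(cache=True)
def movement_chain(
    vx,
    vy,
    ttype,
    phase,
    delta,
    n_burn,
    n_keep,
    seed,
    l0b_init,
    l1b_init,
    l0s_init,
    l1s_init,
    store_speed,
):
    """One MCMC chain for the switching OU movement model.

    A single latent state z_t gates both enhancements (less persistence and
    more velocity variation switch together).  The baseline pair
    (lambda0_beta, lambda0_sigma) and the enhancement pair are each updated
    by a joint random-walk Metropolis step on the z-marginal target.

    Returns ``(l0b, l1b, l0s, l1s, p_draws, speed_draws, accept_rate)``
    where speed_draws (n_keep, 3) holds the per-draw mean over each phase's
    blocks of the state-resolved OU speed (m/s).
    """
    np.random.seed(seed)
    T = vx.shape[0]

    l0b = l0b_init
    l1b = l1b_init
    l0s = l0s_init
    l1s = l1s_init
    p = np.random.random(3)

    l0b_d = np.empty(n_keep)
    l1b_d = np.empty(n_keep)
    l0s_d = np.empty(n_keep)
    l1s_d = np.empty(n_keep)
    p_d = np.empty((n_keep, 3))
    speed_d = np.empty((n_keep, 3))

    nphase = np.zeros(3)
    for t in range(T):
        nphase[phase[t]] += 1.0

    scale0 = 0.2
    scale1 = 0.2
    acc0 = 0
    acc1 = 0
    n_prop = 0
    acc_total = 0.0
    prop_total = 0.0

    rho = np.empty(2)
    var_ar = np.empty(2)
    var_st = np.empty(2)
    lv_ar = np.empty(2)
    lv_st = np.empty(2)
    spd = np.empty(2)
    lf0s = np.empty(T)
    lf1s = np.empty(T)

    for it in range(n_burn + n_keep):
        _movement_regimes(l0b, l1b, l0s, l1s, delta, rho, var_ar, var_st,
                          lv_ar, lv_st)

        # --- latent states (exact Gibbs given lambda, p); the per-block
        #     log-densities are kept to rebuild the marginal likelihood
        #     after the p update without a second pass over the data
        nz = np.zeros(3)
        for t in range(T):
            ph = phase[t]
            pz = p[ph]
            if ttype[t] == 0:
                zt = 1 if np.random.random() < pz else 0
            else:
                lf0 = _movement_block_lf(
                    vx, vy, ttype, t, 0, rho, var_ar, var_st, lv_ar, lv_st
                )
                lf1 = _movement_block_lf(
                    vx, vy, ttype, t, 1, rho, var_ar, var_st, lv_ar, lv_st
                )
                lf0s[t] = lf0
                lf1s[t] = lf1
                dll = lf1 - lf0
                if dll > 0.0:
                    q = pz / (pz + (1.0 - pz) * math.exp(-dll))
                else:
                    q = pz * math.exp(dll) / (pz * math.exp(dll) + 1.0 - pz)
                zt = 1 if np.random.random() < q else 0
            nz[ph] += zt

        # --- phase probabilities
        for ph in range(3):
            p[ph] = np.random.beta(1.0 + nz[ph], 1.0 + nphase[ph] - nz[ph])

        # --- OU parameters: joint RW on the baseline pair, then the
        #     enhancement pair, both against the z-marginal target
        cur = 0.0
        for t in range(T):
            if ttype[t] != 0:
                cur += _mix_ll(lf0s[t], lf1s[t], p[phase[t]])
        n_prop += 1
        prop_total += 2.0

        c0b = l0b + scale0 * np.random.normal()
        c0s = l0s + scale0 * np.random.normal()
        if LAM0_LO < c0b < LAM0_HI and LAM0_LO < c0s < LAM0_HI:
            new = _movement_marginal_ll(
                vx, vy, ttype, phase, p, c0b, l1b, c0s, l1s, delta
            )
            if math.log(np.random.random()) < new - cur:
                l0b = c0b
                l0s = c0s
                cur = new
                acc0 += 1
                acc_total += 1.0

        c1b = l1b + scale1 * np.random.normal()
        c1s = l1s + scale1 * np.random.normal()
        if LAM1_LO <= c1b < LAM1_HI and LAM1_LO <= c1s < LAM1_HI:
            new = _movement_marginal_ll(
                vx, vy, ttype, phase, p, l0b, c1b, l0s, c1s, delta
            )
            if math.log(np.random.random()) < new - cur:
                l1b = c1b
                l1s = c1s
                acc1 += 1
                acc_total += 1.0

        if it < n_burn and n_prop == _ADAPT_WINDOW:
            scale0 = _adapt(scale0, acc0 / _ADAPT_WINDOW)
            scale1 = _adapt(scale1, acc1 / _ADAPT_WINDOW)
            acc0 = 0
            acc1 = 0
            n_prop = 0

        if it >= n_burn:
            k = it - n_burn
            l0b_d[k] = l0b
            l1b_d[k] = l1b
            l0s_d[k] = l0s
            l1s_d[k] = l1s
            for ph in range(3):
                p_d[k, ph] = p[ph]
            if store_speed:
                # refresh z under the just-updated parameters for the speed
                # summaries (valid full-conditional draw)
                _movement_regimes(l0b, l1b, l0s, l1s, delta, rho, var_ar,
                                  var_st, lv_ar, lv_st)
                for zv in range(2):
                    beta = math.exp(l0b + l1b * zv)
                    sig = math.exp(l0s + l1s * zv)
                    spd[zv] = sig * math.sqrt(math.pi / (4.0 * beta))
                sspd = np.zeros(3)
                for t in range(T):
                    ph = phase[t]
                    pz = p[ph]
                    if ttype[t] == 0:
                        zt = 1 if np.random.random() < pz else 0
                    else:
                        lf0 = _movement_block_lf(
                            vx, vy, ttype, t, 0, rho, var_ar, var_st,
                            lv_ar, lv_st
                        )
                        lf1 = _movement_block_lf(
                            vx, vy, ttype, t, 1, rho, var_ar, var_st,
                            lv_ar, lv_st
                        )
                        dll = lf1 - lf0
                        if dll > 0.0:
                            q = pz / (pz + (1.0 - pz) * math.exp(-dll))
                        else:
                            q = pz * math.exp(dll) / (
                                pz * math.exp(dll) + 1.0 - pz
                            )
                        zt = 1 if np.random.random() < q else 0
                    sspd[ph] += spd[zt]
                for ph in range(3):
                    speed_d[k, ph] = sspd[ph] / nphase[ph]

    return l0b_d, l1b_d, l0s_d, l1s_d, p_d, speed_d, acc_total / prop_total


@njit(cache=True)
def _doseresp_loglik(p_obs, x_rl, x_v1, a0, beta, kappa, sig):
    """Truncated-normal regression log-likelihood on the [0, 1] interval."""
    sqrt2 = math.sqrt(2.0)
    ll = 0.0
    for i in range(p_obs.shape[0]):
        m = a0 + kappa * x_v1[i] + beta * x_rl[i]
        zlo = (0.0 - m) / sig
        zhi = (1.0 - m) / sig
        norm = 0.5 * (math.erf(zhi / sqrt2) - math.erf(zlo / sqrt2))
        if norm <= 0.0:
            return -np.inf
        r = (p_obs[i] - m) / sig
        ll += -0.5 * r * r - math.log(sig) - math.log(norm)
    return ll


@njit(cache=True)
def doseresp_chain(
    p_obs,
    x_rl,
    x_v1,
    include_speed,
    a0_prior_mean,
    a0_prior_sd,
    slope_prior_sd,
    n_burn,
    n_keep,
    seed,
):
    """One MCMC chain for the hierarchical exposure-response regression.

    ``x_rl`` and ``x_v1`` are the centred covariates (RL - 160 and
    v1 - mean(v1)).  The intercept prior is N(a0_prior_mean, a0_prior_sd);
    both slopes get N(0, slope_prior_sd).  Returns
    ``(a0, beta, kappa, sigma, accept_rate)`` draw vectors; kappa stays 0
    when ``include_speed`` is false.
    """
    np.random.seed(seed)
    a0 = 0.0
    for i in range(p_obs.shape[0]):
        a0 += p_obs[i]
    a0 /= p_obs.shape[0]
    beta = 0.0
    kappa = 0.0
    sig = 0.3

    a0_d = np.empty(n_keep)
    beta_d = np.empty(n_keep)
    kappa_d = np.empty(n_keep)
    sig_d = np.empty(n_keep)

    s_a0 = 0.1
    s_beta = 0.01
    s_kappa = 0.05
    s_sig = 0.1
    acc = np.zeros(4)
    n_prop = 0
    acc_total = 0.0
    prop_total = 0.0
    a0_var2 = 2.0 * a0_prior_sd * a0_prior_sd
    slope_var2 = 2.0 * slope_prior_sd * slope_prior_sd
    n_param = 4.0 if include_speed else 3.0

    cur = _doseresp_loglik(p_obs, x_rl, x_v1, a0, beta, kappa, sig)
    for it in range(n_burn + n_keep):
        n_prop += 1
        prop_total += n_param

        cand = a0 + s_a0 * np.random.normal()
        new = _doseresp_loglik(p_obs, x_rl, x_v1, cand, beta, kappa, sig)
        da = a0 - a0_prior_mean
        dc = cand - a0_prior_mean
        dprior = (da * da - dc * dc) / a0_var2
        if math.log(np.random.random()) < new - cur + dprior:
            a0 = cand
            cur = new
            acc[0] += 1
            acc_total += 1.0

        cand = beta + s_beta * np.random.normal()
        new = _doseresp_loglik(p_obs, x_rl, x_v1, a0, cand, kappa, sig)
        dprior = (beta * beta - cand * cand) / slope_var2
        if math.log(np.random.random()) < new - cur + dprior:
            beta = cand
            cur = new
            acc[1] += 1
            acc_total += 1.0

        if include_speed:
            cand = kappa + s_kappa * np.random.normal()
            new = _doseresp_loglik(p_obs, x_rl, x_v1, a0, beta, cand, sig)
            dprior = (kappa * kappa - cand * cand) / slope_var2
            if math.log(np.random.random()) < new - cur + dprior:
                kappa = cand
                cur = new
                acc[2] += 1
                acc_total += 1.0

        cand = sig + s_sig * np.random.normal()
        if 0.0 < cand < 1.0:
            new = _doseresp_loglik(p_obs, x_rl, x_v1, a0, beta, kappa, cand)
            if math.log(np.random.random()) < new - cur:
                sig = cand
                cur = new
                acc[3] += 1
                acc_total += 1.0

        if it < n_burn and n_prop == _ADAPT_WINDOW:
            s_a0 = _adapt(s_a0, acc[0] / _ADAPT_WINDOW)
            s_beta = _adapt(s_beta, acc[1] / _ADAPT_WINDOW)
            s_kappa = _adapt(s_kappa, acc[2] / _ADAPT_WINDOW)
            s_sig = _adapt(s_sig, acc[3] / _ADAPT_WINDOW)
            acc[:] = 0.0
            n_prop = 0

        if it >= n_burn:
            k = it - n_burn
            a0_d[k] = a0
            beta_d[k] = beta
            kappa_d[k] = kappa
            sig_d[k] = sig

    return a0_d, beta_d, kappa_d, sig_d, acc_total / prop_total
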