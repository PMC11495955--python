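"""Independent oracles used by the tests.

These re-derive expected quantities by brute force (dense-grid quadrature,
closed forms, direct enumeration) without touching the package's samplers,
so that agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np


def poisson_latent_quadrature(
    y: np.ndarray,
    phase_idx: np.ndarray,
    l0_grid: np.ndarray,
    l1_grid: np.ndarray,
    n_p: int = 101,
) -> dict[str, float]:
    """Posterior means of the two-state Poisson latent model by quadrature.

    The latent states are summed out analytically per block (the per-block
    likelihood is the two-term mixture), so the marginal likelihood
    factorises over phases:  L = prod_ph  L_ph(lambda0, lambda1, p_ph).
    Each phase's p is integrated on a midpoint grid; (lambda0, lambda1) on
    the supplied grids (flat priors cancel).
    """
    pg = (np.arange(n_p) + 0.5) / n_p
    L0, L1 = np.meshgrid(l0_grid, l1_grid, indexing="ij")
    mu0 = np.exp(L0)[..., None]
    mu1 = np.exp(L0 + L1)[..., None]
    ev = []  # per phase: (integral over p of L, log-scale offset)
    sv = []  # per phase: (integral of p * L, same offset)
    for ph in range(3):
        log_l = np.zeros(L0.shape + (n_p,))
        for yt in y[phase_idx == ph]:
            lf0 = yt * np.log(mu0) - mu0 - math.lgamma(yt + 1)
            lf1 = yt * np.log(mu1) - mu1 - math.lgamma(yt + 1)
            log_l += np.log((1 - pg) * np.exp(lf0) + pg * np.exp(lf1))
        off = log_l.max()
        lin = np.exp(log_l - off)
        ev.append((lin.sum(-1), off))
        sv.append(((lin * pg).sum(-1), off))
    log_evidence = sum(np.log(np.maximum(e, 1e-300)) + off for e, off in ev)
    w = np.exp(log_evidence - log_evidence.max())
    w /= w.sum()
    out = {"lambda0": float((w * L0).sum()), "lambda1": float((w * L1).sum())}
    for ph, name in enumerate(("p_pre", "p_exp", "p_post")):
        ratio = sv[ph][0] / np.maximum(ev[ph][0], 1e-300)
        out[name] = float((w * ratio).sum())
    return out


def ou_ar1_loglik_grid(
    vx: np.ndarray,
    vy: np.ndarray,
    beta_grid: np.ndarray,
    sigma_grid: np.ndarray,
    delta: float,
) -> tuple[float, float]:
    """Grid-search MLE of a single-regime OU velocity AR(1).

    Vectorised closed-form evaluation of the transition log-likelihood on
    a (beta, sigma) grid; returns the maximising pair.
    """
    B, S = np.meshgrid(beta_grid, sigma_grid, indexing="ij")
    rho = np.exp(-B * delta)
    var = S**2 / (2.0 * B) * (1.0 - rho**2)
    n = len(vx) - 1
    dx2 = ((vx[1:, None, None] - rho * vx[:-1, None, None]) ** 2).sum(axis=0)
    dy2 = ((vy[1:, None, None] - rho * vy[:-1, None, None]) ** 2).sum(axis=0)
    ll = -(dx2 + dy2) / (2.0 * var) - n * np.log(2.0 * math.pi * var)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(beta_grid[i]), float(sigma_grid[j])
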