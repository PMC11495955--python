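"""Focal-subgroup movement: block velocities and the correlated random walk.

The focal subgroup's drone-derived track (planar metres, ~1 Hz) is reduced
to one velocity per 5 s analysis block.  Block velocities follow the exact
discretisation of a 2D Ornstein-Uhlenbeck (OU) velocity process

    dv = -beta * v dt + sigma dW,

which is an AR(1) on the block grid: ``v_t | v_{t-1} ~ N(rho v_{t-1},
tau^2 (1 - rho^2) I)`` with ``rho = exp(-beta * delta)`` and stationary
variance ``tau^2 = sigma^2 / (2 beta)`` per component.  ``beta`` (1/s)
controls directional persistence (larger beta, less persistence) and
``sigma`` the variability of velocity.  Group speed is derived from the two
parameters as the mean of the stationary Rayleigh speed distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import PhaseSchedule

#: conversion from m/s to km/h for reported speeds
MS_TO_KMH = 3.6


@dataclass(frozen=True)
class MovementParams:
    """Log-scale baseline/enhancement parameterisation of (beta, sigma).

    ``beta = exp(lambda0_beta + lambda1_beta * z)`` and likewise for sigma,
    with z the per-block latent state.  Both enhancements are constrained
    non-negative so the enhanced state always has less directional
    persistence (larger beta) and more velocity variation (larger sigma).
    """

    lambda0_beta: float
    lambda1_beta: float
    lambda0_sigma: float
    lambda1_sigma: float

    def __post_init__(self) -> None:
        if self.lambda1_beta < 0 or self.lambda1_sigma < 0:
            raise ValueError("enhancements lambda1_* must be non-negative")

    def beta(self, z: int) -> float:
        return math.exp(self.lambda0_beta + self.lambda1_beta * z)

    def sigma(self, z: int) -> float:
        return math.exp(self.lambda0_sigma + self.lambda1_sigma * z)


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Check a track table (columns time_s, x_m, y_m) for basic sanity."""
    for col in ("time_s", "x_m", "y_m"):
        if col not in track.columns:
            raise ValueError(f"track table lacks required column {col!r}")
    t = track["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"track times must be strictly increasing (row {row})")
    xy = track[["x_m", "y_m"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("track coordinates must be finite")
    return track


def blockify_track(track: pd.DataFrame, schedule: PhaseSchedule) -> pd.DataFrame:
    """Average velocity of each analysis block from a position track.

    For each block the velocity is the displacement between the track
    samples nearest the block's start and end boundaries (each within 1 s
    of the boundary), divided by the block duration.  Blocks without a
    sample near either boundary are marked unobserved.

    Returns a table with columns ``block_index, vx, vy, observed``.
    """
    validate_track(track)
    t = track["time_s"].to_numpy(dtype=float)
    x = track["x_m"].to_numpy(dtype=float)
    y = track["y_m"].to_numpy(dtype=float)
    if t[-1] < schedule.pre_start or t[0] > schedule.post_end:
        raise ValueError("track lies entirely outside the phase schedule")

    bounds = np.append(schedule.block_starts(), schedule.post_end)
    idx = np.searchsorted(t, bounds)
    n = schedule.n_blocks
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    obs = np.zeros(n, dtype=bool)

    def nearest(bound: float, i: int) -> int | None:
        best, best_d = None, 1.0 + 1e-9
        for j in (i - 1, i):
            if 0 <= j < t.size:
                d = abs(t[j] - bound)
                if d < best_d:
                    best, best_d = j, d
        return best

    near = [nearest(b, i) for b, i in zip(bounds, idx)]
    for k in range(n):
        j0, j1 = near[k], near[k + 1]
        if j0 is None or j1 is None or j0 == j1:
            continue
        vx[k] = (x[j1] - x[j0]) / schedule.block_dur
        vy[k] = (y[j1] - y[j0]) / schedule.block_dur
        obs[k] = True
    return pd.DataFrame(
        {"block_index": np.arange(n), "vx": vx, "vy": vy, "observed": obs}
    )


def ou_block_loglik(
    v_curr: tuple[float, float],
    v_prev: tuple[float, float],
    beta_ou: float,
    sigma_ou: float,
    delta: float,
) -> float:
    """Log-density of one OU velocity transition over a lag of ``delta`` s.

    ``v_curr ~ N2(rho * v_prev, tau^2 (1 - rho^2) I)`` with
    ``rho = exp(-beta_ou * delta)`` and ``tau^2 = sigma_ou^2 / (2 beta_ou)``;
    the two components are independent and identically distributed
    (isotropic motion).
    """
    if beta_ou <= 0 or sigma_ou <= 0 or delta <= 0:
        raise ValueError("beta_ou, sigma_ou and delta must be positive")
    rho = math.exp(-beta_ou * delta)
    var = sigma_ou**2 / (2.0 * beta_ou) * (1.0 - rho * rho)
    dx = v_curr[0] - rho * v_prev[0]
    dy = v_curr[1] - rho * v_prev[1]
    return -(dx * dx + dy * dy) / (2.0 * var) - math.log(2.0 * math.pi * var)


def derive_speed(beta_ou: float, sigma_ou: float) -> float:
    """Mean speed implied by the OU parameters, m/s.

    The stationary velocity is isotropic bivariate normal with per-component
    variance ``tau^2 = sigma^2 / (2 beta)``, so the speed is Rayleigh with
    mean ``tau sqrt(pi/2) = sigma sqrt(pi / (4 beta))``.
    """
    if beta_ou <= 0 or sigma_ou <= 0:
        raise ValueError("beta_ou and sigma_ou must be positive")
    return sigma_ou * math.sqrt(math.pi / (4.0 * beta_ou))
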