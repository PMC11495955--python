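"""Two-state latent Bayesian models for CEE behavioural response variables.

Each response variable (whistle counts, subgroup counts, block velocities)
is modelled with a per-5-s-block binary latent state z_t: a baseline state
and an "enhanced" state whose response mean is inflated through a log link,

    log(mean_t) = lambda0 + lambda1 * z_t,        lambda1 >= 0,
    z_t ~ Bernoulli(p_phase[t]),

with flat U(-30, 30) priors on lambda0, U(0, 30) on lambda1 and U(0, 1) on
each phase probability.  The observation family is Poisson (subgroup
counts), zero-truncated normal (whistle counts) or the switching OU
velocity model (movement; one shared z_t gates both the persistence and
the velocity-variation enhancement).  Inference is Metropolis-within-Gibbs
MCMC over several chains.

Behavioural change between phases is quantified by the separation of the
posterior distributions of the phase probabilities: the probability of
response compares p_exposure with p_pre-exposure, the probability of
persistence compares p_post-exposure with p_pre-exposure.  The statistic is
0.5 for identical posteriors, 1 for disjoint ones, and a change is declared
detected when it exceeds 0.9.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import _samplers
from .movement import MS_TO_KMH
from .schedule import PHASES, PhaseSchedule

FAMILIES = ("poisson", "trunc_normal", "normal_movement")
_FAMILY_CODES = {"poisson": _samplers.FAMILY_POISSON,
                 "trunc_normal": _samplers.FAMILY_TRUNC_NORMAL}

logger = logging.getLogger("ceeresponse")

#: posterior-separation threshold above which a change is declared detected
DETECTION_THRESHOLD = 0.9
#: convergence flag threshold for the potential scale reduction factor
PSRF_THRESHOLD = 1.05


def z_full_conditional(
    y_t: float | None,
    p: float,
    params: Mapping[str, float],
    family: str,
) -> float:
    """Posterior probability that a single block is in the enhanced state.

    ``p * f(y | enhanced) / (p * f(y | enhanced) + (1-p) * f(y | baseline))``;
    an unobserved block (``y_t`` None or NaN) contributes no likelihood and
    the full conditional reduces to the phase probability ``p``.

    ``params`` carries ``lambda0``/``lambda1`` and, for the truncated-normal
    family, ``obs_sd``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if family not in ("poisson", "trunc_normal"):
        raise ValueError(f"unsupported family {family!r}")
    if y_t is None or (isinstance(y_t, float) and math.isnan(y_t)):
        return p
    mu0 = math.exp(params["lambda0"])
    mu1 = math.exp(params["lambda0"] + params["lambda1"])
    if family == "poisson":
        f1 = stats.poisson.pmf(y_t, mu1)
        f0 = stats.poisson.pmf(y_t, mu0)
    else:
        sd = params["obs_sd"]
        if sd <= 0:
            raise ValueError("obs_sd must be positive")
        f1 = stats.truncnorm.pdf(y_t, -mu1 / sd, np.inf, loc=mu1, scale=sd)
        f0 = stats.truncnorm.pdf(y_t, -mu0 / sd, np.inf, loc=mu0, scale=sd)
    num = p * f1
    den = num + (1.0 - p) * f0
    if den == 0.0:
        return p
    return float(num / den)


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws of one latent-state fit.

    ``params`` maps parameter names to (chains, samples) arrays; ``p`` has
    shape (chains, samples, 3) in phase order pre/exp/post.  For the
    movement family ``speed`` holds per-draw phase-mean OU speeds (m/s).
    """

    family: str
    params: dict[str, np.ndarray]
    p: np.ndarray
    speed: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.p < 0.0) | (self.p > 1.0)):
            raise ValueError("phase probability draws must lie in [0, 1]")

    @property
    def n_chains(self) -> int:
        return self.p.shape[0]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def p_pooled(self, phase: str) -> np.ndarray:
        return self.p[:, :, PHASES.index(phase)].reshape(-1)


@dataclass
class CeeResult:
    """Summary of one fitted response variable for one CEE."""

    metric: str
    family: str
    phase_means: dict[str, tuple[float, float]]
    p_response: float
    response_direction: str
    p_persistence: float
    persistence_direction: str
    detected_exposure: bool
    detected_post: bool
    psrf: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "family": self.family,
            "phase_means": {k: list(v) for k, v in self.phase_means.items()},
            "p_response": self.p_response,
            "response_direction": self.response_direction,
            "p_persistence": self.p_persistence,
            "persistence_direction": self.persistence_direction,
            "detected_exposure": self.detected_exposure,
            "detected_post": self.detected_post,
            "psrf": self.psrf,
        }


class LatentStateModel(BaseEstimator):
    """Two-state latent Bayesian model fitted by Metropolis-within-Gibbs.

    Parameters
    ----------
    family
        ``"poisson"``, ``"trunc_normal"`` or ``"normal_movement"``.
    n_samples, n_burnin
        Kept and discarded iterations per chain (defaults match the study
        protocol of 100 000 each; reduce for exploratory fits).
    n_chains
        Number of chains started from overdispersed initial values.
    seed
        Base seed; chain seeds are spawned deterministically from it.
    block_dur
        Analysis block length in seconds (movement transitions only).
    likelihood_stride
        Let only every ``stride``-th block contribute likelihood (states
        are still drawn everywhere).  Subgroup scans observed every 2 min
        are tiled across 5 s blocks and enter the likelihood once per
        block by default, replicating the scan design's pseudo-
        replication; ``likelihood_stride=24`` restores a once-per-
        observation likelihood for sensitivity analysis.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Post-burn-in draws across chains.
    psrf_ : dict
        Potential scale reduction factor per parameter.
    accept_rate_ : float
        Mean Metropolis acceptance rate across chains.
    """

    def __init__(
        self,
        family: str = "poisson",
        n_samples: int = 100_000,
        n_burnin: int = 100_000,
        n_chains: int = 3,
        seed: int = 0,
        block_dur: float = 5.0,
        store_speed: bool = True,
        likelihood_stride: int = 1,
    ):
        self.family = family
        self.n_samples = n_samples
        self.n_burnin = n_burnin
        self.n_chains = n_chains
        self.seed = seed
        self.block_dur = block_dur
        self.store_speed = store_speed
        self.likelihood_stride = likelihood_stride

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame, schedule: PhaseSchedule | None = None):
        """Fit the model to a block series (counts) or block velocities.

        ``data`` must carry a ``phase`` column, or ``schedule`` must be
        given to supply the phase of each block.  Counts need columns
        ``value``/``observed``; movement needs ``vx``/``vy``/``observed``.
        """
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        phase_idx = self._phase_index(data, schedule)
        obs = data["observed"].to_numpy(dtype=bool)
        if self.likelihood_stride > 1:
            if "block_index" in data.columns:
                idx = data["block_index"].to_numpy()
            else:
                idx = np.arange(len(data))
            obs = obs & (idx % self.likelihood_stride == 0)
        for code, name in enumerate(PHASES):
            if not np.any(obs & (phase_idx == code)):
                raise ValueError(f"phase {name!r} has no observed blocks")

        seeds = self._chain_seeds()
        if self.family == "normal_movement":
            self._fit_movement(data, phase_idx, obs, seeds)
        else:
            self._fit_counts(data, phase_idx, obs, seeds)
        self.psrf_ = {
            name: psrf(draws) for name, draws in self.draws_.params.items()
        }
        for k, ph in enumerate(PHASES):
            self.psrf_[f"p_{ph}"] = psrf(self.draws_.p[:, :, k])
        cfg = self.draws_.config
        cfg_hash = hashlib.md5(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:10]
        logger.info(
            "latent fit family=%s seed=%s config=%s accept=%.3f max_psrf=%.3f",
            self.family, self.seed, cfg_hash, self.accept_rate_,
            max(self.psrf_.values()),
        )
        return self

    def _phase_index(self, data, schedule):
        if "phase" in data.columns:
            codes = np.array(
                [PHASES.index(ph) for ph in data["phase"]], dtype=np.int64
            )
            return codes
        if schedule is None:
            raise ValueError("data lacks a phase column and no schedule given")
        if len(data) != schedule.n_blocks:
            raise ValueError("data length does not match the schedule grid")
        return schedule.phase_index()

    def _chain_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % (2**31 - 1) for s in ss.generate_state(self.n_chains)]

    def _fit_counts(self, data, phase_idx, obs, seeds):
        y = data["value"].to_numpy(dtype=float)
        if np.any(y[obs] < 0):
            raise ValueError("count responses must be non-negative")
        if np.any(obs & ~np.isfinite(y)):
            raise ValueError("observed blocks must carry finite values")
        y = np.where(obs, y, 0.0)
        fam = _FAMILY_CODES[self.family]
        ybar = float(y[obs].mean())
        ysd = float(y[obs].std()) if obs.sum() > 1 else 1.0

        lam0 = np.empty((self.n_chains, self.n_samples))
        lam1 = np.empty_like(lam0)
        sd = np.empty_like(lam0)
        p = np.empty((self.n_chains, self.n_samples, 3))
        acc = 0.0
        for c, s in enumerate(seeds):
            rng = np.random.default_rng(s)
            lam0_init = float(
                np.clip(math.log(ybar + 0.1) + rng.normal(0, 1.0), -29, 29)
            )
            lam1_init = float(np.clip(abs(rng.normal(0, 1.0)) + 0.05, 0.01, 29))
            sd_init = float(np.clip(ysd + abs(rng.normal(0, 1.0)), 0.1, 29))
            out = _samplers.counts_chain(
                y, obs, phase_idx, fam, self.n_burnin, self.n_samples, s,
                lam0_init, lam1_init, sd_init,
            )
            lam0[c], lam1[c], sd[c], p[c] = out[0], out[1], out[2], out[3]
            acc += out[4]
        params = {"lambda0": lam0, "lambda1": lam1}
        if self.family == "trunc_normal":
            params["obs_sd"] = sd
        self.draws_ = PosteriorDraws(
            family=self.family, params=params, p=p, config=self._config(seeds)
        )
        self.accept_rate_ = acc / self.n_chains

    def _fit_movement(self, data, phase_idx, obs, seeds):
        vx = data["vx"].to_numpy(dtype=float)
        vy = data["vy"].to_numpy(dtype=float)
        vx = np.where(obs, vx, 0.0)
        vy = np.where(obs, vy, 0.0)
        # 2 = AR transition, 1 = stationary (start / after a gap), 0 = none
        ttype = np.zeros(len(vx), dtype=np.int64)
        ttype[obs] = 1
        prev_obs = np.concatenate([[False], obs[:-1]])
        ttype[obs & prev_obs] = 2

        # moment-based starting points: a global AR(1) fit for the decay
        # rate and a two-group split of block speeds for the two regimes'
        # stationary variances (stationary E|v|^2 = 2 tau^2); per-chain
        # jitter keeps the starts overdispersed
        sp = np.hypot(vx[obs], vy[obs])
        both = obs & np.concatenate([[False], obs[:-1]])
        if both.sum() >= 3:
            r = np.corrcoef(
                np.concatenate([vx[both], vy[both]]),
                np.concatenate([np.roll(vx, 1)[both], np.roll(vy, 1)[both]]),
            )[0, 1]
        else:
            r = 0.4
        r = float(np.clip(r, 0.05, 0.95))
        beta_hat = -math.log(r) / self.block_dur
        sp2 = np.sort(sp**2)
        lo = sp2[: max(len(sp2) // 2, 1)]
        hi = sp2[len(sp2) // 2:]
        tau2_lo = max(float(lo.mean()) / 2.0, 1e-3)
        tau2_hi = max(float(hi.mean()) / 2.0, tau2_lo * 1.2)

        names = ("lambda0_beta", "lambda1_beta", "lambda0_sigma", "lambda1_sigma")
        params = {n: np.empty((self.n_chains, self.n_samples)) for n in names}
        p = np.empty((self.n_chains, self.n_samples, 3))
        speed = np.empty((self.n_chains, self.n_samples, 3))
        acc = 0.0
        for c, s in enumerate(seeds):
            rng = np.random.default_rng(s)
            l0b = float(
                np.clip(math.log(beta_hat) + rng.normal(0, 0.5), -29, 29)
            )
            l0s = float(
                np.clip(0.5 * math.log(2.0 * beta_hat * tau2_lo)
                        + rng.normal(0, 0.3), -29, 29)
            )
            l1b = float(np.clip(abs(rng.normal(0, 0.5)) + 0.02, 0.01, 29))
            l1s = float(
                np.clip(0.5 * math.log(tau2_hi / tau2_lo)
                        + abs(rng.normal(0, 0.3)), 0.01, 29)
            )
            out = _samplers.movement_chain(
                vx, vy, ttype, phase_idx, self.block_dur,
                self.n_burnin, self.n_samples, s, l0b, l1b, l0s, l1s,
                self.store_speed,
            )
            for n, arr in zip(names, out[:4]):
                params[n][c] = arr
            p[c], speed[c] = out[4], out[5]
            acc += out[6]
        self.draws_ = PosteriorDraws(
            family=self.family, params=params, p=p,
            speed=speed if self.store_speed else None,
            config=self._config(seeds),
        )
        self.accept_rate_ = acc / self.n_chains

    def _config(self, seeds) -> dict:
        return {
            "family": self.family,
            "n_samples": self.n_samples,
            "n_burnin": self.n_burnin,
            "n_chains": self.n_chains,
            "seed": self.seed,
            "chain_seeds": list(seeds),
        }

    # ------------------------------------------------------------------
    def result(self, metric: str = "response") -> CeeResult:
        """Summarise the fit as detection flags and phase means."""
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        d = self.draws_
        p_resp, dir_resp = response_probability(d, "exp", "pre")
        p_pers, dir_pers = response_probability(d, "post", "pre")
        if self.family == "normal_movement":
            means = {
                ph: phase_speed(d, ph, units="kmh") for ph in PHASES
            }
        else:
            means = {ph: phase_mean(d, ph) for ph in PHASES}
        return CeeResult(
            metric=metric,
            family=self.family,
            phase_means=means,
            p_response=p_resp,
            response_direction=dir_resp,
            p_persistence=p_pers,
            persistence_direction=dir_pers,
            detected_exposure=detect_change(p_resp),
            detected_post=detect_change(p_pers),
            psrf=dict(self.psrf_),
        )


def fit_latent_state(
    data: pd.DataFrame,
    family: str = "poisson",
    n_samples: int = 100_000,
    n_burnin: int = 100_000,
    n_chains: int = 3,
    seed: int = 0,
    schedule: PhaseSchedule | None = None,
) -> PosteriorDraws:
    """Functional wrapper around :class:`LatentStateModel`."""
    model = LatentStateModel(
        family=family, n_samples=n_samples, n_burnin=n_burnin,
        n_chains=n_chains, seed=seed,
    ).fit(data, schedule=schedule)
    return model.draws_


# ----------------------------------------------------------------------
# posterior functionals


def phase_mean(draws: PosteriorDraws, phase: str) -> tuple[float, float]:
    """Posterior mean and sd of the phase-average response level.

    The phase mean is ``exp(lambda0 + lambda1 * p_phase)`` evaluated per
    MCMC draw; averaging over draws propagates the joint posterior.
    """
    lam0 = draws.pooled("lambda0")
    lam1 = draws.pooled("lambda1")
    p = draws.p_pooled(phase)
    vals = np.exp(lam0 + lam1 * p)
    return float(vals.mean()), float(vals.std())


def phase_speed(
    draws: PosteriorDraws, phase: str, units: str = "ms"
) -> tuple[float, float]:
    """Posterior mean and sd of the phase-average group speed (movement fits).

    Per draw, speed is averaged over the phase's blocks with each block's
    OU parameters resolved at its sampled state.
    """
    if draws.speed is None:
        raise ValueError("speed summaries require a movement-family fit")
    vals = draws.speed[:, :, PHASES.index(phase)].reshape(-1)
    if units == "kmh":
        vals = vals * MS_TO_KMH
    elif units != "ms":
        raise ValueError("units must be 'ms' or 'kmh'")
    return float(vals.mean()), float(vals.std())


def response_probability(
    draws: PosteriorDraws, phase_a: str = "exp", phase_b: str = "pre"
) -> tuple[float, str]:
    """Degree of separation between two phase-probability posteriors.

    The larger of the two directional proportions Pr[p_a > p_b] and
    Pr[p_a < p_b] over pooled draws, with ties at equality split evenly;
    0.5 means the posteriors are indistinguishable, 1 means disjoint.  The
    direction reports which inequality wins ("increase" = enhanced state
    more probable in ``phase_a``).
    """
    pa = draws.p_pooled(phase_a)
    pb = draws.p_pooled(phase_b)
    return separation_statistic(pa, pb)


def separation_statistic(
    pa: np.ndarray, pb: np.ndarray
) -> tuple[float, str]:
    """Separation of two posterior samples (see response_probability)."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.size == 0 or pa.shape != pb.shape:
        raise ValueError("need two non-empty samples of equal length")
    gt = float(np.mean(pa > pb))
    ties = float(np.mean(pa == pb))
    p_up = gt + 0.5 * ties
    if p_up >= 0.5:
        return p_up, "increase"
    return 1.0 - p_up, "decrease"


def detect_change(p: float) -> bool:
    """Change detected iff the separation statistic strictly exceeds 0.9."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p > DETECTION_THRESHOLD


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n) with m >= 2 chains of equal length n.
    Returns 1.0 when the draws carry no variance at all (degenerate but
    trivially converged chains).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("psrf needs at least two chains of equal length")
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = float(chains.var(axis=1, ddof=1).mean())
    b_over_n = float(means.var(ddof=1))
    var_hat = (n - 1) / n * w + b_over_n
    if b_over_n == 0.0 or var_hat == 0.0:
        # chains indistinguishable (or wholly degenerate): converged
        return 1.0
    if w == 0.0:
        return float("inf")
    return float(math.sqrt(var_hat / w))
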