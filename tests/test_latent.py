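import numpy as np
import pandas as pd
import pytest

import ceeresponse as cr
from ceeresponse.latent import PosteriorDraws, separation_statistic


# ----------------------------------------------------------------------
# z full conditional


def test_z_full_conditional_prior_mass_and_cancellation():
    params = {"lambda0": 0.0, "lambda1": 1.0}
    assert cr.z_full_conditional(3, 0.0, params, "poisson") == 0.0
    assert cr.z_full_conditional(3, 1.0, params, "poisson") == 1.0
    # identical densities leave the prior untouched
    same = {"lambda0": 0.5, "lambda1": 0.0}
    assert cr.z_full_conditional(2, 0.37, same, "poisson") == pytest.approx(0.37)
    # unobserved block returns the phase probability
    assert cr.z_full_conditional(None, 0.42, params, "poisson") == 0.42
    assert cr.z_full_conditional(float("nan"), 0.42, params, "poisson") == 0.42


def test_z_full_conditional_poisson_density_ratio():
    # 0.5 * Pois(3; 4) / (0.5 * Pois(3; 4) + 0.5 * Pois(3; 1)) = 0.7611
    params = {"lambda0": 0.0, "lambda1": np.log(4.0)}
    got = cr.z_full_conditional(3, 0.5, params, "poisson")
    assert got == pytest.approx(0.7611, abs=1e-3)


def test_z_full_conditional_matches_toy_fit_states(toy_poisson_fit):
    # the sampler's z probabilities follow the same density ratio: a clear
    # exposure-level observation should be near-certainly enhanced under
    # the posterior-mean parameters
    d = toy_poisson_fit.draws_
    params = {
        "lambda0": d.pooled("lambda0").mean(),
        "lambda1": d.pooled("lambda1").mean(),
    }
    q = cr.z_full_conditional(7, d.p_pooled("exp").mean(), params, "poisson")
    assert q > 0.95


# ----------------------------------------------------------------------
# fitting


def test_fit_is_deterministic_under_fixed_seed(toy_poisson_series):
    kw = dict(n_samples=500, n_burnin=500, n_chains=3, seed=11)
    a = cr.LatentStateModel("poisson", **kw).fit(toy_poisson_series)
    b = cr.LatentStateModel("poisson", **kw).fit(toy_poisson_series)
    np.testing.assert_array_equal(a.draws_.p, b.draws_.p)
    np.testing.assert_array_equal(
        a.draws_.pooled("lambda0"), b.draws_.pooled("lambda0")
    )


def test_fit_rejects_phase_without_observations(toy_poisson_series):
    data = toy_poisson_series.copy()
    data.loc[data.phase == "exp", "observed"] = False
    data.loc[data.phase == "exp", "value"] = np.nan
    with pytest.raises(ValueError, match="exp"):
        cr.LatentStateModel("poisson", n_samples=100, n_burnin=100).fit(data)


def test_unobserved_values_do_not_enter_the_posterior(toy_poisson_series):
    # changing the (ignored) stored value of an unobserved block must not
    # change the draws
    data = toy_poisson_series.copy()
    data.loc[8, "observed"] = False
    kw = dict(n_samples=2000, n_burnin=1000, n_chains=2, seed=4)
    a = cr.LatentStateModel("poisson", **kw).fit(data)
    data2 = data.copy()
    data2.loc[8, "value"] = 999.0  # unobserved: sampler must ignore it
    b = cr.LatentStateModel("poisson", **kw).fit(data2)
    np.testing.assert_array_equal(a.draws_.p, b.draws_.p)


def test_enhanced_consistent_evidence_raises_p_exp(toy_poisson_series):
    # appending exposure observations at the enhanced level cannot decrease
    # the posterior mean of p_exp
    kw = dict(n_samples=4000, n_burnin=2000, n_chains=3, seed=9)
    base = cr.LatentStateModel("poisson", **kw).fit(toy_poisson_series)
    extra = pd.DataFrame(
        {
            "block_index": [9, 10, 11],
            "phase": ["exp"] * 3,
            "value": [7.0, 6.0, 8.0],
            "observed": True,
        }
    )
    grown = pd.concat([toy_poisson_series, extra], ignore_index=True)
    more = cr.LatentStateModel("poisson", **kw).fit(grown)
    assert (
        more.draws_.p_pooled("exp").mean()
        >= base.draws_.p_pooled("exp").mean() - 0.02
    )


def test_lambda1_zero_data_leave_p_near_its_uniform_prior(schedule):
    # simulator/analysis consistency: with no enhancement in the data the
    # phase probabilities stay close to the U(0,1) prior (mean 1/2)
    truth = cr.SimTruth(lambda0=np.log(2), lambda1=0.0,
                        p_pre=0.5, p_exp=0.5, p_post=0.5, seed=23)
    blocks, _ = cr.simulate_counts(schedule, "poisson", truth)
    m = cr.LatentStateModel(
        "poisson", n_samples=3000, n_burnin=3000, n_chains=3, seed=8
    ).fit(blocks)
    for ph in ("pre", "exp", "post"):
        assert 0.35 <= m.draws_.p_pooled(ph).mean() <= 0.65


# ----------------------------------------------------------------------
# posterior functionals


def _degenerate_draws(lam0, lam1, p_by_phase):
    n = len(np.atleast_1d(lam0))
    arr = lambda x: np.broadcast_to(np.asarray(x, float), (1, n)).copy()
    p = np.stack(
        [arr(p_by_phase[ph]) for ph in ("pre", "exp", "post")], axis=-1
    )
    return PosteriorDraws(
        family="poisson",
        params={"lambda0": arr(lam0), "lambda1": arr(lam1)},
        p=p,
    )


def test_phase_mean_closed_forms():
    d = _degenerate_draws(0.0, 0.0, {"pre": 0.3, "exp": 0.9, "post": 0.1})
    assert cr.phase_mean(d, "exp") == (pytest.approx(1.0), pytest.approx(0.0))
    d = _degenerate_draws(np.log(10), 0.5, {"pre": 1.0, "exp": 1.0, "post": 1.0})
    mean, sd = cr.phase_mean(d, "pre")
    assert mean == pytest.approx(10 * np.exp(0.5), abs=1e-6)
    d = _degenerate_draws([0.0, 0.0], [1.0, 1.0],
                          {"pre": [0.0, 1.0], "exp": [0, 0], "post": [0, 0]})
    mean, _ = cr.phase_mean(d, "pre")
    assert mean == pytest.approx((1 + np.e) / 2)


def test_separation_statistic_limits_and_ties():
    rng = np.random.default_rng(0)
    same = rng.beta(5, 5, 100_000)
    other = rng.beta(5, 5, 100_000)
    p, _ = separation_statistic(same, other)
    assert p == pytest.approx(0.5, abs=0.01)
    lo = rng.uniform(0.0, 0.4, 10_000)
    hi = rng.uniform(0.6, 1.0, 10_000)
    p, direction = separation_statistic(hi, lo)
    assert p == 1.0 and direction == "increase"
    p, direction = separation_statistic(lo, hi)
    assert p == 1.0 and direction == "decrease"
    ties = np.full(1000, 0.5)
    p, _ = separation_statistic(ties, ties)
    assert p == 0.5


def test_separation_statistic_direction_relabelling_invariance():
    rng = np.random.default_rng(1)
    a, b = rng.beta(2, 5, 5000), rng.beta(5, 2, 5000)
    p_ab, d_ab = separation_statistic(a, b)
    p_ba, d_ba = separation_statistic(b, a)
    assert p_ab == pytest.approx(p_ba)
    assert {d_ab, d_ba} == {"increase", "decrease"}
    assert 0.5 <= p_ab <= 1.0


def test_detect_change_strict_threshold():
    assert cr.detect_change(0.91)
    assert not cr.detect_change(0.90)
    assert not cr.detect_change(0.50)
    with pytest.raises(ValueError):
        cr.detect_change(1.2)


def test_psrf_identical_separated_and_mixed_chains(toy_poisson_fit):
    same = np.tile(np.sin(np.arange(500.0)), (3, 1))
    assert cr.psrf(same) == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(2)
    apart = np.stack(
        [rng.normal(0, 0.01, 400), rng.normal(0, 0.01, 400),
         rng.normal(10, 0.01, 400)]
    )
    assert cr.psrf(apart) > 1.1
    with pytest.raises(ValueError):
        cr.psrf(np.zeros((1, 100)))
    # long well-mixed chains on the toy fit converge
    assert all(v < 1.05 for v in toy_poisson_fit.psrf_.values())


def test_psrf_agrees_with_arviz_rank_normalised_rhat():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    mixed = rng.normal(size=(3, 2000))
    apart = mixed + np.array([[0.0], [0.0], [5.0]])
    az_mixed = float(az.rhat(az.convert_to_dataset(mixed)).x)
    az_apart = float(az.rhat(az.convert_to_dataset(apart)).x)
    assert cr.psrf(mixed) < 1.05 and az_mixed < 1.05
    assert cr.psrf(apart) > 1.5 and az_apart > 1.5


def test_result_summary_flags(toy_poisson_fit):
    res = toy_poisson_fit.result(metric="subgroups")
    assert res.p_response >= 0.5 and res.p_persistence >= 0.5
    assert res.response_direction == "increase"
    assert res.detected_exposure == (res.p_response > 0.9)
    for ph in ("pre", "exp", "post"):
        assert res.phase_means[ph][0] > 0
    # the exposure phase mean clearly exceeds the pre-exposure mean
    assert res.phase_means["exp"][0] > res.phase_means["pre"][0]


def test_likelihood_stride_widens_pseudo_replicated_posteriors(schedule):
    # tiled 2 min subgroup scans enter the likelihood once per 5 s block;
    # a once-per-observation likelihood must give a wider p posterior
    truth = cr.SimTruth(lambda0=np.log(2), lambda1=np.log(2.5),
                        p_pre=0.2, p_exp=0.7, p_post=0.4, seed=31)
    blocks, _ = cr.simulate_counts(schedule, "poisson", truth,
                                   observation_interval=120.0)
    kw = dict(n_samples=3000, n_burnin=3000, n_chains=2, seed=12)
    tiled = cr.LatentStateModel("poisson", **kw).fit(blocks)
    once = cr.LatentStateModel("poisson", likelihood_stride=24, **kw).fit(blocks)
    assert once.draws_.p_pooled("exp").std() > tiled.draws_.p_pooled("exp").std()
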