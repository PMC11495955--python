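import numpy as np
import pandas as pd
import pytest

import ceeresponse as cr
from ceeresponse.simulate import simulate_block_velocities


def test_simulated_poisson_blocks_match_log_link_mean(schedule):
    big = cr.make_phase_schedule(20000, 20000, 10000, 5)  # 10^4 blocks
    truth = cr.SimTruth(lambda0=np.log(2), lambda1=0.0,
                        p_pre=0.5, p_exp=0.5, p_post=0.5, seed=1)
    blocks, _ = cr.simulate_counts(big, "poisson", truth)
    v = blocks["value"]
    se = np.sqrt(v.var() / len(v))
    assert abs(v.mean() - 2.0) < 3 * se


def test_poisson_phase_means_converge_to_plug_in_value():
    big = cr.make_phase_schedule(20000, 20000, 10000, 5)
    truth = cr.SimTruth(lambda0=0.0, lambda1=2.0,
                        p_pre=0.0, p_exp=1.0, p_post=0.3, seed=2)
    blocks, _ = cr.simulate_counts(big, "poisson", truth)
    exp_vals = blocks.loc[blocks.phase == "exp", "value"]
    se = np.sqrt(exp_vals.var() / len(exp_vals))
    assert abs(exp_vals.mean() - np.e**2) < 3 * se
    # phase means converge to exp(lambda0 + lambda1 * p_phase) grid-wide
    post_vals = blocks.loc[blocks.phase == "post", "value"]
    expected_post = 0.3 * np.e**2 + 0.7  # mixture mean, p_post = 0.3
    se = np.sqrt(post_vals.var() / len(post_vals))
    assert abs(post_vals.mean() - expected_post) < 3 * se


def test_truncated_normal_counts_are_non_negative(schedule):
    truth = cr.SimTruth(lambda0=np.log(0.5), lambda1=1.0, seed=3)
    blocks, _ = cr.simulate_counts(schedule, "trunc_normal", truth, obs_sd=5.0)
    assert (blocks["value"] >= 0).all()


def test_unknown_family_rejected(schedule):
    with pytest.raises(ValueError, match="family"):
        cr.simulate_counts(schedule, "negbin", cr.SimTruth())


def test_subgroup_values_constant_between_observations(schedule):
    truth = cr.SimTruth(lambda0=np.log(2), lambda1=np.log(2), seed=4)
    blocks, _ = cr.simulate_counts(
        schedule, "poisson", truth, observation_interval=120.0
    )
    v = blocks["value"].to_numpy()
    stride = 24  # 120 s / 5 s
    for k in range(0, len(v), stride):
        assert (v[k:k + stride] == v[k]).all()
    assert float(v[0]).is_integer()


def test_seed_determinism_of_all_simulators(schedule):
    truth = cr.SimTruth(seed=7)
    t1, z1 = cr.simulate_track(schedule, truth)
    t2, z2 = cr.simulate_track(schedule, truth)
    pd.testing.assert_frame_equal(t1, t2)
    assert (z1 == z2).all()
    b1, _ = cr.simulate_counts(schedule, "poisson", truth)
    b2, _ = cr.simulate_counts(schedule, "poisson", truth)
    pd.testing.assert_frame_equal(b1, b2)
    d1 = cr.simulate_cee(seed=11)
    d2 = cr.simulate_cee(seed=11)
    pd.testing.assert_frame_equal(d1.track, d2.track)
    pd.testing.assert_frame_equal(d1.whistles, d2.whistles)
    assert d1.pings.to_frame().equals(d2.pings.to_frame())


def test_track_rejects_invalid_parameters(schedule):
    with pytest.raises(ValueError):
        cr.SimTruth(beta_ou=(0.0, 0.2))
    with pytest.raises(ValueError):
        cr.SimTruth(beta_ou=(0.3, 0.2))  # enhanced less persistent required
    with pytest.raises(ValueError):
        cr.simulate_track(schedule, cr.SimTruth(), dt=7.0)  # 7 !| 5


def test_single_regime_track_matches_ou_closed_forms():
    # lag-5 s autocorrelation e^(-beta*delta) and Rayleigh mean speed
    big = cr.make_phase_schedule(20000, 20000, 20000, 5)
    truth = cr.SimTruth(
        lambda0=0.0, lambda1=0.0, p_pre=0.0, p_exp=0.0, p_post=0.0,
        beta_ou=(0.2, 0.2), sigma_ou=(0.5, 0.5), seed=11,
    )
    track, _ = cr.simulate_track(big, truth)
    v = np.diff(track[["x_m", "y_m"]].to_numpy(), axis=0)  # 1 Hz velocities
    lag = 5
    ac = np.corrcoef(v[:-lag, 0], v[lag:, 0])[0, 1]
    assert ac == pytest.approx(np.exp(-0.2 * 5), abs=0.03)
    speed = np.hypot(v[:, 0], v[:, 1])
    assert speed.mean() == pytest.approx(
        0.5 * np.sqrt(np.pi / (4 * 0.2)), rel=0.03
    )


def test_apply_missingness_policies(schedule):
    n = schedule.n_blocks
    base = pd.DataFrame(
        {
            "block_index": np.arange(n),
            "phase": schedule.block_phases(),
            "value": np.ones(n),
            "observed": True,
        }
    )
    # a single change at block 100 blanks the 6 preceding blocks
    series = base.copy()
    series.loc[100:, "value"] = 2.0
    out = cr.apply_missingness(series, "pre_change_30s")
    assert (~out["observed"].to_numpy()[94:100]).all()
    assert out["observed"].to_numpy()[:94].all()
    assert out["observed"].to_numpy()[100:].all()
    assert out.loc[~out["observed"], "value"].isna().all()
    # a constant series is untouched
    out = cr.apply_missingness(base, "pre_change_30s")
    assert out["observed"].all()
    # random blocks keeps ~f of the grid
    out = cr.apply_missingness(base, "random_blocks", seed=5, f=0.5)
    k = out["observed"].sum()
    assert abs(k - n / 2) < 3 * np.sqrt(n * 0.25)
    # identity
    pd.testing.assert_frame_equal(cr.apply_missingness(base, "none"), base)
    with pytest.raises(ValueError):
        cr.apply_missingness(base, "random_blocks", f=1.5)


def test_simulate_cee_bundles_consistent_streams():
    ds = cr.simulate_cee(seed=3, cee_type="mfas_navy")
    assert len(ds.track) == 1801
    assert len(ds.whistles) == 360 and len(ds.subgroups) == 360
    assert len(ds.pings.pings) == 24
    assert ds.pings.source_level == 215.0
    rls = ds.pings.spls()
    assert (rls > 109).all() and (rls < 160).all()
    ctrl = cr.simulate_cee(seed=3, cee_type="control")
    assert not ctrl.pings.transmitted
    assert ctrl.truth["whistles"]["p_exp"] == ctrl.truth["whistles"]["p_pre"]


def test_block_velocity_simulator_agrees_with_track_route(schedule):
    truth = cr.SimTruth(seed=21)
    bv, z1 = simulate_block_velocities(schedule, truth)
    track, z2 = cr.simulate_track(schedule, truth)
    via_track = cr.blockify_track(track, schedule)
    assert (z1 == z2).all()
    np.testing.assert_allclose(
        bv[["vx", "vy"]].to_numpy(), via_track[["vx", "vy"]].to_numpy(),
        atol=1e-9,
    )
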