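import numpy as np
import pandas as pd
import pytest

from hennorm.features import (
    count_no_transition_days,
    validate_transition_log,
    zone_occupancy,
)
from hennorm.simulate import (
    ConfigError,
    SimConfig,
    make_population,
    simulate_daily_scores,
    simulate_transition_log,
    simulate_welfare,
)


# --- configuration validation -----------------------------------------------


def test_config_rejects_bad_sizes():
    with pytest.raises(ConfigError):
        SimConfig(n_hens=1)
    with pytest.raises(ConfigError):
        SimConfig(n_days=2)
    with pytest.raises(ConfigError):
        SimConfig(var_slope=-1.0)


def test_config_rejects_bad_correlations():
    bad = np.eye(4)
    bad[0, 1] = 0.5  # asymmetric
    with pytest.raises(ConfigError):
        SimConfig(re_correlations=bad)
    sing = np.ones((4, 4))  # unit diagonal but singular
    with pytest.raises(ConfigError):
        SimConfig(re_correlations=sing)


# --- determinism --------------------------------------------------------------


def test_simulation_is_deterministic():
    cfg = SimConfig(n_hens=6, n_days=5, seed=123)
    t1, t2 = make_population(cfg), make_population(cfg)
    assert np.array_equal(t1.effects, t2.effects)
    pd.testing.assert_frame_equal(
        simulate_daily_scores(t1, cfg), simulate_daily_scores(t2, cfg)
    )
    pd.testing.assert_frame_equal(
        simulate_transition_log(t1, cfg), simulate_transition_log(t2, cfg)
    )


def test_different_seeds_differ():
    cfg = SimConfig(n_hens=6, n_days=5, seed=1)
    t1 = make_population(cfg)
    t2 = make_population(cfg.with_(seed=2))
    assert not np.array_equal(t1.effects, t2.effects)


# --- trivial (noise-free) populations ----------------------------------------


def test_zero_variance_scores_equal_fixed_part():
    cfg = SimConfig(
        n_hens=4, n_days=6,
        var_intercept=0.0, var_slope=0.0, var_slope2=0.0, var_dispersion=0.0,
        resid_sd_baseline=-30.0,  # residual SD ~ 1e-13
        seed=3,
    )
    truth = make_population(cfg)
    assert np.allclose(truth.effects, 0.0)
    scores = simulate_daily_scores(truth, cfg)
    want = (
        cfg.beta_time * scores["time"]
        + cfg.beta_time2 * scores["time2"]
        + cfg.beta_treatment * scores["treatment"]
        + cfg.beta_temperature * scores["temperature"]
    )
    assert np.allclose(scores["pc1"], want, atol=1e-10)


def test_true_summaries_match_closed_forms():
    cfg = SimConfig(var_intercept=11.0, var_dispersion=0.0606,
                    resid_sd_baseline=float(np.log(np.sqrt(14.0))))
    truth = make_population(cfg)
    denom = 11.0 + np.exp(np.log(14.0) + 2 * 0.0606)
    assert truth.true_repeatability == pytest.approx(11.0 / denom)
    assert truth.true_cvp == pytest.approx(np.sqrt(np.expm1(0.0606)))


# --- moment recovery ----------------------------------------------------------


def test_effect_moments_recovered_at_large_n():
    R = np.eye(4)
    R[0, 1] = R[1, 0] = -0.6
    cfg = SimConfig(
        n_hens=4000, n_days=3,
        var_intercept=11.0, var_slope=4.0, var_slope2=0.0, var_dispersion=1.0,
        re_correlations=R, seed=11,
    )
    truth = make_population(cfg)
    e = truth.effects
    assert np.var(e[:, 0], ddof=1) == pytest.approx(11.0, rel=0.1)
    assert np.var(e[:, 1], ddof=1) == pytest.approx(4.0, rel=0.1)
    assert np.all(e[:, 2] == 0.0)
    r01 = np.corrcoef(e[:, 0], e[:, 1])[0, 1]
    assert r01 == pytest.approx(-0.6, abs=0.05)


def test_empirical_draws_hit_target_moments_exactly():
    R = np.eye(4)
    R[0, 1] = R[1, 0] = -0.79
    cfg = SimConfig(
        n_hens=40, n_days=3,
        var_intercept=2.0, var_slope=0.5, var_slope2=0.0, var_dispersion=0.0,
        re_correlations=R, empirical=True, seed=5,
    )
    e = make_population(cfg).effects
    assert np.allclose(e.mean(axis=0), 0.0, atol=1e-10)
    cov = np.cov(e[:, :2], rowvar=False, ddof=1)
    target = np.array([[2.0, -0.79 * np.sqrt(2.0 * 0.5)],
                       [-0.79 * np.sqrt(2.0 * 0.5), 0.5]])
    assert np.allclose(cov, target, atol=1e-10)
    assert np.all(e[:, 2:] == 0.0)


# --- transition logs ----------------------------------------------------------


def test_transition_log_is_valid_and_consistent_with_dwell():
    cfg = SimConfig(n_hens=3, n_days=4, seed=7, p_no_transition_day=0.0)
    truth = make_population(cfg)
    log, dwell = simulate_transition_log(truth, cfg, return_dwell=True)
    validated = validate_transition_log(log)
    assert len(validated) == len(log)  # no consecutive duplicates emitted

    cal = cfg.calendar
    dwell = dwell.set_index(["hen_id", "day"])
    for hen in truth.hen_ids:
        for day in cal.day_indices:
            occ = zone_occupancy(log, cal, hen, day)
            want = dwell.loc[(hen, day)]
            for zone in occ.index:
                assert occ[zone] == pytest.approx(want[zone], abs=1e-6), (hen, day, zone)
            assert occ.sum() == pytest.approx(cal[day].lit_seconds)


def test_forced_no_transition_days_are_counted():
    cfg = SimConfig(n_hens=3, n_days=5, seed=9, p_no_transition_day=1.0)
    truth = make_population(cfg)
    log = simulate_transition_log(truth, cfg)
    counts = count_no_transition_days(log, cfg.calendar)
    # the first three days are forced transition-free; later days essentially
    # always contain at least one move
    assert (counts.loc[truth.hen_ids] == 3).all()


def test_winter_garden_only_after_opening():
    cfg = SimConfig(n_hens=6, n_days=10, seed=13, p_no_transition_day=0.0)
    truth = make_population(cfg)
    log = simulate_transition_log(truth, cfg)
    cal = cfg.calendar
    wg = log[log["zone"] == "winter_garden"]
    assert len(wg) > 0
    for ts in wg["timestamp"]:
        day = cal.day_of(ts)
        sched = cal[day]
        assert sched.wg_available
        assert ts >= pd.Timestamp(sched.wg_open)


# --- welfare ------------------------------------------------------------------


def test_welfare_noise_free_is_exact_linear_function():
    cfg = SimConfig(n_hens=8, n_days=3, seed=4,
                    welfare_pen_sd=0.0, welfare_resid_sd=0.0)
    truth = make_population(cfg)
    pred = pd.Series(np.linspace(-0.4, 0.4, 8), index=truth.hen_ids)
    ntd = pd.Series(np.arange(8) % 3, index=truth.hen_ids)
    wf = simulate_welfare(truth, cfg, pred, ntd).set_index("hen_id")
    want = 36.0 + 23.54 * pred + 5.12 * ntd
    assert np.allclose(wf["kbf"], np.clip(want, 0, 100))


def test_welfare_clipping_is_rare_at_defaults():
    cfg = SimConfig(n_hens=200, n_days=3, seed=21)
    truth = make_population(cfg)
    pred = pd.Series(-truth.d, index=truth.hen_ids)
    ntd = pd.Series(np.zeros(200), index=truth.hen_ids)
    wf = simulate_welfare(truth, cfg, pred, ntd)
    assert wf.attrs["clipped_fraction"] < 0.01
    assert ((wf["kbf"] >= 0) & (wf["kbf"] <= 100)).all()


def test_welfare_requires_all_hens():
    cfg = SimConfig(n_hens=4, n_days=3, seed=2)
    truth = make_population(cfg)
    pred = pd.Series(np.zeros(3), index=truth.hen_ids[:3])
    ntd = pd.Series(np.zeros(4), index=truth.hen_ids)
    with pytest.raises(KeyError, match="predictability"):
        simulate_welfare(truth, cfg, pred, ntd)
    with pytest.raises(KeyError, match="ntd"):
        simulate_welfare(truth, cfg, ntd, pred)
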