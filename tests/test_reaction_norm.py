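import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hennorm import reaction_norm as rn
from hennorm.simulate import SimConfig, make_population, simulate_daily_scores


def anova_data(n_hens=15, n_days=20, v_id=4.0, v_res=2.0, seed=0):
    """Balanced one-way layout with known variance components."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(v_id), n_hens)
    rows = []
    for h in range(n_hens):
        for d in range(1, n_days + 1):
            rows.append(
                {
                    "hen_id": f"hen_{h}",
                    "day": d,
                    "time": float(d),
                    "time2": float(d) ** 2,
                    "pc1": 1.5 + a[h] + rng.normal(0, np.sqrt(v_res)),
                }
            )
    return pd.DataFrame(rows)


# --- spec validation ----------------------------------------------------------


def test_model_spec_validation():
    with pytest.raises(ValueError, match="random part"):
        rn.ModelSpec(random="rs3")
    with pytest.raises(ValueError, match="time2 requires time"):
        rn.ModelSpec(fixed=("time2",))


def test_interval_estimate_must_bracket():
    with pytest.raises(ValueError):
        rn.IntervalEstimate(point=0.9, lower95=0.1, upper95=0.5, n_draws=10)


# --- RI model against the balanced-ANOVA closed form --------------------------


def test_ri_fit_matches_anova_closed_form():
    data = anova_data()
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    g = data.groupby("hen_id")["pc1"]
    n_per = int(g.size().iloc[0])
    msw = float(((data["pc1"] - g.transform("mean")) ** 2).sum()
                / (g.ngroups * (n_per - 1)))
    msb = float(n_per * ((g.mean() - data["pc1"].mean()) ** 2).sum()
                / (g.ngroups - 1))
    assert fit.v_res == pytest.approx(msw, rel=1e-4)
    assert fit.v_id == pytest.approx((msb - msw) / n_per, rel=1e-3)
    assert fit.fe_params["Intercept"] == pytest.approx(data["pc1"].mean(), rel=1e-6)
    assert fit.converged and not fit.boundary
    # conditional modes are the shrunken group means
    shrink = fit.v_id / (fit.v_id + fit.v_res / n_per)
    want = shrink * (g.mean() - data["pc1"].mean())
    got = fit.re_modes["intercept"].reindex(want.index)
    assert np.allclose(got, want, atol=1e-6)


def test_ri_reml_loglike_matches_statsmodels():
    data = anova_data(seed=3)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=("time",), random="ri"))
    X = np.column_stack([np.ones(len(data)), data["time"].to_numpy(float)])
    ll = rn._ri_reml_loglike(
        data["pc1"].to_numpy(float), X, data["hen_id"].to_numpy(),
        fit.v_id, fit.v_res,
    )
    assert ll == pytest.approx(fit.llf, abs=1e-4)


def test_ri_boundary_when_no_hen_effect():
    data = anova_data(v_id=0.0, v_res=1.0, n_hens=10, n_days=30, seed=5)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    assert fit.v_id < 0.05
    est = rn.adjusted_repeatability(fit, seed=0)
    assert est.point < 0.05
    assert est.lower95 <= est.point <= est.upper95


# --- variance decomposition and R² --------------------------------------------


def test_variance_decomposition_and_r_squared():
    cfg = SimConfig(
        n_hens=40, n_days=30, seed=8,
        var_intercept=2.0, var_slope=0.0, var_slope2=0.0, var_dispersion=0.0,
        re_correlations=np.eye(4), resid_sd_baseline=0.0,
    )
    truth = make_population(cfg)
    scores = simulate_daily_scores(truth, cfg)
    fit = rn.fit_mixed(scores, rn.ModelSpec(random="ri"))
    assert fit.v_id + fit.v_res == pytest.approx(
        2.0 + np.exp(0.0) ** 2, rel=0.35
    )
    r2m, r2c = rn.r_squared(fit)
    assert 0 < r2m < r2c < 1
    # fixed effects explain a visible share here (strong time trend)
    assert r2m > 0.05
    # residuals are centred and smaller than the raw response spread
    assert abs(fit.resid.mean()) < 0.05
    assert fit.resid.var() < scores["pc1"].var()


# --- the RI/RS1/RS2 ladder and LRT --------------------------------------------


def test_lrt_detects_real_slope_variance():
    cfg = SimConfig(
        n_hens=50, n_days=30, seed=2,
        beta_treatment=0.0, beta_temperature=0.0,
        var_intercept=1.0, var_slope=0.01, var_slope2=0.0, var_dispersion=0.0,
        re_correlations=np.eye(4), resid_sd_baseline=0.0,
    )
    truth = make_population(cfg)
    scores = simulate_daily_scores(truth, cfg)
    spec = dict(fixed=("time", "time2"))
    m0 = rn.fit_mixed(scores, rn.ModelSpec(random="ri", **spec))
    m1 = rn.fit_mixed(scores, rn.ModelSpec(random="rs1", **spec))
    stat, df, p = rn.likelihood_ratio_test(m0, m1)
    assert df == 2
    assert stat > 0 and p < 1e-4


def test_lrt_errors():
    data = anova_data(n_hens=8, n_days=10)
    ri = rn.fit_mixed(data, rn.ModelSpec(fixed=("time",), random="ri"))
    rs1 = rn.fit_mixed(data, rn.ModelSpec(fixed=("time",), random="rs1"))
    with pytest.raises(ValueError, match="not nested"):
        rn.likelihood_ratio_test(rs1, ri)
    ri_t = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    with pytest.raises(ValueError, match="identical"):
        rn.likelihood_ratio_test(ri_t, rs1)
    short = rn.fit_mixed(data.iloc[:-5], rn.ModelSpec(fixed=("time",), random="ri"))
    with pytest.raises(ValueError, match="different data"):
        rn.likelihood_ratio_test(short, rs1)


def test_lrt_null_stat_is_bounded():
    # no slope variance in truth: the statistic may be 0 (p = 1) or small
    data = anova_data(n_hens=10, n_days=12, seed=11)
    ri = rn.fit_mixed(data, rn.ModelSpec(fixed=("time",), random="ri"))
    rs1 = rn.fit_mixed(data, rn.ModelSpec(fixed=("time",), random="rs1"))
    stat, df, p = rn.likelihood_ratio_test(ri, rs1)
    assert stat >= 0 and 0 <= p <= 1


# --- repeatability ------------------------------------------------------------


def test_adjusted_repeatability_recovery_and_errors():
    data = anova_data(n_hens=40, n_days=30, v_id=4.0, v_res=6.0, seed=7)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    est = rn.adjusted_repeatability(fit, seed=1)
    assert est.point == pytest.approx(0.4, abs=0.1)
    assert est.lower95 < est.point < est.upper95
    assert 0.0 < est.upper95 - est.lower95 < 0.4
    rs1 = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="rs1"))
    with pytest.raises(ValueError, match="RI model"):
        rn.adjusted_repeatability(rs1)


# --- BLUPs --------------------------------------------------------------------


def test_blups_track_true_hen_effects():
    data = anova_data(n_hens=30, n_days=25, v_id=4.0, v_res=1.0, seed=4)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    per_hen, corr = rn.blup_summaries(fit, seed=0)
    means = per_hen[per_hen["term"] == "intercept"].set_index("hen_id")["mean"]
    true_means = data.groupby("hen_id")["pc1"].mean()
    rho = stats.spearmanr(means, true_means.reindex(means.index)).statistic
    assert rho > 0.95
    assert (per_hen["sd"] > 0).all()
    assert corr.empty  # RI model has a single random term


def test_blup_correlations_reported_for_rs1():
    cfg = SimConfig(
        n_hens=40, n_days=30, seed=6,
        beta_treatment=0.0, beta_temperature=0.0,
        var_intercept=1.0, var_slope=0.01, var_slope2=0.0, var_dispersion=0.0,
        resid_sd_baseline=0.0,
    )
    truth = make_population(cfg)
    scores = simulate_daily_scores(truth, cfg)
    fit = rn.fit_mixed(scores, rn.ModelSpec(fixed=("time", "time2"), random="rs1"))
    _, corr = rn.blup_summaries(fit)
    assert list(corr["term_a"]) == ["intercept"]
    assert -1 <= corr["correlation"].iloc[0] <= 1


# --- population peak day ------------------------------------------------------


def _fit_with_betas(b1, b2):
    data = anova_data(n_hens=6, n_days=10)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=("time", "time2"), random="ri"))
    fit.fe_params["time"] = b1
    fit.fe_params["time2"] = b2
    return fit


def test_population_peak_day_cases():
    assert rn.population_peak_day(_fit_with_betas(0.078, -0.001)) == pytest.approx(39.0)
    assert rn.population_peak_day(_fit_with_betas(0.0, -0.001)) == 0.0
    with pytest.warns(UserWarning, match="no interior maximum"):
        assert np.isnan(rn.population_peak_day(_fit_with_betas(0.1, 0.002)))
    data = anova_data(n_hens=6, n_days=10)
    fit = rn.fit_mixed(data, rn.ModelSpec(fixed=(), random="ri"))
    with pytest.raises(ValueError, match="time and time2"):
        rn.population_peak_day(fit)


def test_fit_mixed_input_errors():
    data = anova_data(n_hens=4, n_days=5)
    bad = data.copy()
    bad.loc[0, "pc1"] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        rn.fit_mixed(bad, rn.ModelSpec(fixed=(), random="ri"))
    one = data[data["hen_id"] == "hen_0"]
    with pytest.raises(ValueError, match="at least 2 hens"):
        rn.fit_mixed(one, rn.ModelSpec(fixed=(), random="ri"))
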