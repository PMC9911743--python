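"""Calibrated parameter-recovery runs.

Each function simulates a synthetic population whose generating values are
set to the quantities the analysis is supposed to estimate, runs the
corresponding stage of the package end to end, and returns the recovered
estimate together with the problem size.  They are shared by the acceptance
script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dispersion, reaction_norm, welfare
from .simulate import SimConfig, make_population, simulate_daily_scores, simulate_welfare


def _corr(r01: float = 0.0) -> np.ndarray:
    R = np.eye(4)
    R[0, 1] = R[1, 0] = r01
    return R


def _rep_seeds(seed: int, n_reps: int) -> list[int]:
    ss = np.random.SeedSequence([seed, 17])
    return [int(s) for s in ss.generate_state(n_reps) >> 1]  # keep below 2^31


def repeatability_recovery(
    seed: int, n_hens: int = 80, n_days: int = 47, n_reps: int = 3
) -> dict:
    """RI model on data with intercept variance 11 and residual variance 14
    (true variance share 0.44); returns the adjusted repeatability point,
    averaged over replicate populations to damp finite-population noise."""
    points = []
    ci = None
    n_obs = 0
    for s in _rep_seeds(seed, n_reps):
        cfg = SimConfig(
            n_hens=n_hens, n_days=n_days,
            beta_time=0.0, beta_time2=0.0, beta_treatment=0.0,
            beta_temperature=0.0,
            var_intercept=11.0, var_slope=0.0, var_slope2=0.0,
            var_dispersion=0.0,
            re_correlations=np.eye(4),
            resid_sd_baseline=float(np.log(np.sqrt(14.0))),
            empirical=True,
            seed=s,
        )
        truth = make_population(cfg)
        scores = simulate_daily_scores(truth, cfg)
        fit = reaction_norm.fit_mixed(
            scores, reaction_norm.ModelSpec(fixed=(), random="ri")
        )
        est = reaction_norm.adjusted_repeatability(fit, seed=s)
        points.append(est.point)
        if ci is None:
            ci = (est.lower95, est.upper95)
        n_obs = fit.n_obs
    return {
        "value": float(np.mean(points)),
        "lower95": ci[0],
        "upper95": ci[1],
        "n": n_obs * n_reps,
    }


def intercept_slope_corr_recovery(
    seed: int, n_hens: int = 80, n_days: int = 47, n_reps: int = 3
) -> dict:
    """RS1 model on data generated with intercept-slope correlation -0.79."""
    vals = []
    n_obs = 0
    for s in _rep_seeds(seed, n_reps):
        cfg = SimConfig(
            n_hens=n_hens, n_days=n_days,
            beta_time=0.0, beta_time2=0.0, beta_treatment=0.0,
            beta_temperature=0.0,
            var_intercept=1.0, var_slope=2e-3, var_slope2=0.0,
            var_dispersion=0.0,
            re_correlations=_corr(-0.79),
            resid_sd_baseline=0.0,
            empirical=True,
            seed=s,
        )
        truth = make_population(cfg)
        scores = simulate_daily_scores(truth, cfg)
        fit = reaction_norm.fit_mixed(
            scores, reaction_norm.ModelSpec(fixed=("time",), random="rs1")
        )
        cov = fit.cov_re.to_numpy()
        vals.append(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
        n_obs = fit.n_obs
    return {"value": float(np.mean(vals)), "n": n_obs * n_reps}


def peak_day_recovery(
    seed: int, n_hens: int = 80, n_days: int = 47, n_reps: int = 8
) -> dict:
    """RS2 model on data with fixed time coefficients 0.078 / -0.001 (vertex
    at day 39); returns -beta_time / (2 beta_time2) computed from the
    replicate-averaged coefficients (the ratio of single-replicate estimates
    is heavy-tailed because beta_time2 is small)."""
    b1s, b2s = [], []
    n_obs = 0
    for s in _rep_seeds(seed, n_reps):
        cfg = SimConfig(
            n_hens=n_hens, n_days=n_days,
            beta_time=0.078, beta_time2=-0.001, beta_treatment=0.0,
            beta_temperature=0.0,
            var_intercept=1.0, var_slope=0.0, var_slope2=0.0,
            var_dispersion=0.0,
            re_correlations=np.eye(4),
            resid_sd_baseline=0.0,
            seed=s,
        )
        truth = make_population(cfg)
        scores = simulate_daily_scores(truth, cfg)
        fit = reaction_norm.fit_mixed(
            scores, reaction_norm.ModelSpec(fixed=("time", "time2"), random="rs2")
        )
        b1s.append(float(fit.fe_params["time"]))
        b2s.append(float(fit.fe_params["time2"]))
        n_obs = fit.n_obs
    value = -float(np.mean(b1s)) / (2.0 * float(np.mean(b2s)))
    return {"value": value, "n": n_obs * n_reps}


def cvp_recovery(
    seed: int,
    n_hens: int = 80,
    n_days: int = 47,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_reps: int = 4,
) -> dict:
    """DHGLM on data with among-hen dispersion variance 0.0606 (true CVp
    0.25); returns the CVp posterior mean, averaged over replicate
    populations to damp finite-population noise."""
    vals = []
    ci = None
    n_obs = 0
    for s in _rep_seeds(seed, n_reps):
        cfg = SimConfig(
            n_hens=n_hens, n_days=n_days,
            beta_time=0.0, beta_time2=0.0, beta_treatment=0.0,
            beta_temperature=0.0,
            var_intercept=1.0, var_slope=0.0, var_slope2=0.0,
            var_dispersion=0.0606,
            re_correlations=np.eye(4),
            resid_sd_baseline=0.0,
            empirical=True,
            seed=s,
        )
        truth = make_population(cfg)
        scores = simulate_daily_scores(truth, cfg)
        spec = dispersion.DHGLMSpec(
            mean_fixed=(), disp_fixed=(), mean_random=("intercept",),
            n_chains=n_chains, n_iter=n_iter, seed=s, store_loglik=False,
        )
        fit = dispersion.fit_dhglm(scores, spec)
        est = dispersion.coefficient_of_variation_predictability(fit)
        vals.append(est.point)
        if ci is None:
            ci = (est.lower95, est.upper95)
        n_obs = len(fit.y)
    return {
        "value": float(np.mean(vals)),
        "lower95": ci[0],
        "upper95": ci[1],
        "n": n_obs * n_reps,
    }


def welfare_coefficient_recovery(
    seed: int,
    n_hens: int = 80,
    n_days: int = 47,
    n_iter: int = 8000,
    n_burn: int = 2000,
    thin: int = 6,
    n_chains: int = 2,
    n_reps: int = 3,
) -> dict:
    """Bivariate model on welfare scores generated with a coefficient of
    23.54 on predictability and 5.12 on the no-transition-day count
    (Gaussian noise SD 10); returns both posterior means, averaged over
    replicate populations to damp finite-population noise."""
    pred_vals, ntd_vals = [], []
    for s in _rep_seeds(seed, n_reps):
        cfg = SimConfig(
            n_hens=n_hens, n_days=n_days,
            var_dispersion=0.0625,  # predictability = -d with SD exactly 0.25
            welfare_pen_sd=0.0, welfare_resid_sd=10.0,
            empirical=True,
            seed=s,
        )
        truth = make_population(cfg)
        scores = simulate_daily_scores(truth, cfg)
        rng = np.random.default_rng(np.random.SeedSequence([s, 5]))
        # predictability: the hen's sign-flipped dispersion intercept (SD ~0.25)
        pred = pd.Series(-truth.d, index=truth.hen_ids, name="predictability")
        ntd = pd.Series(
            rng.binomial(3, 0.1293, n_hens), index=truth.hen_ids,
            name="no_transition_days",
        )
        wf = simulate_welfare(truth, cfg, pred, ntd)
        pred_table = pd.DataFrame(
            {"predictability": pred, "predictability_sd": 0.0}
        ).rename_axis("hen_id")
        fit = welfare.fit_bivariate(
            scores, wf, pred_table, ntd,
            n_iter=n_iter, n_burn=n_burn, thin=thin, n_chains=n_chains, seed=s,
        )
        summ = welfare.fixed_effect_summary(fit).set_index(["response", "term"])
        pred_vals.append(summ.loc[("kbf", "predictability"), "posterior_mean"])
        ntd_vals.append(summ.loc[("kbf", "no_transition_days"), "posterior_mean"])
    return {
        "predictability": float(np.mean(pred_vals)),
        "no_transition_days": float(np.mean(ntd_vals)),
        "n": n_hens * n_reps,
    }
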