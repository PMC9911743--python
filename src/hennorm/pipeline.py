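"""End-to-end orchestration: simulate → extract features → composite score →
reaction norms → dispersion model → welfare association.

Each stage writes its outputs as delimited text under the run directory and
the next stage reads them back from disk, so any stage can be re-run or
replaced by real data in the same formats.  All randomness derives from one
root seed, split per stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dispersion, features, reaction_norm, score, welfare
from .barn import BarnCalendar
from .simulate import (
    SimConfig,
    make_population,
    simulate_transition_log,
    simulate_welfare,
)

log = logging.getLogger("hennorm")

STAGES = ("simulate", "features", "score", "fit_rn", "fit_dhglm", "fit_welfare")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str | Path
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    dhglm_chains: int = 2
    dhglm_iter: int = 8000
    bivariate_iter: int = 4000
    bivariate_burn: int = 1000
    bivariate_thin: int = 3
    bivariate_chains: int = 2
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.outdir = Path(self.outdir)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    sim = cfg.sim.with_(seed=cfg.seed)
    truth = make_population(sim)
    tlog = simulate_transition_log(truth, sim)
    features.write_transition_log(tlog, out / "transition_log.csv")
    sim.calendar.to_yaml(out / "calendar.yaml")
    truth.covariates.to_csv(out / "hen_covariates.csv")
    truth.temperature.to_csv(out / "temperature.csv")
    # ground truth kept apart from pipeline inputs, for recovery checks only
    truth.effects_frame().to_csv(out / "truth_effects.csv")
    wf = simulate_welfare(
        truth,
        sim,
        pd.Series(-truth.d, index=truth.hen_ids),
        _ntd_from_log(tlog, sim.calendar),
    )
    wf.to_csv(out / "welfare.csv", index=False)
    log.info("simulate: %d hens, %d transition records", sim.n_hens, len(tlog))


def _ntd_from_log(tlog, calendar) -> pd.Series:
    return features.count_no_transition_days(tlog, calendar).fillna(0)


def _stage_features(cfg: RunConfig, out: Path) -> None:
    tlog = features.read_transition_log(out / "transition_log.csv")
    calendar = BarnCalendar.from_yaml(out / "calendar.yaml")
    daily = features.daily_variables(tlog, calendar)
    daily.to_csv(out / "daily_vars.csv", index=False)
    ntd = features.count_no_transition_days(tlog, calendar)
    ntd.to_csv(out / "no_transition_days.csv")
    log.info("features: %d hen-days (%d complete)", len(daily),
             int(daily["complete"].sum()))


def _stage_score(cfg: RunConfig, out: Path) -> None:
    daily = pd.read_csv(out / "daily_vars.csv")
    cov = pd.read_csv(out / "hen_covariates.csv").set_index("hen_id")
    temp = pd.read_csv(out / "temperature.csv").set_index("day")["temperature"]
    subset = score.weekly_subset(daily)
    model = score.fit_pca(subset)
    model.to_yaml(out / "pca_model.yaml")
    table = score.project_pc1(model, daily, covariates=cov, temperature=temp)
    table.to_csv(out / "scores.csv", index=False)
    log.info("score: PC1 explains %.0f%% of variance; %d retained components",
             100 * model.explained_fraction()[0], model.n_retained)


def _stage_fit_rn(cfg: RunConfig, out: Path, report: dict) -> None:
    scores = pd.read_csv(out / "scores.csv")
    fixed = tuple(
        c for c in reaction_norm.DEFAULT_FIXED if scores[c].nunique() > 1
    )
    fits = {}
    for rung in reaction_norm.RANDOM_LADDER:
        fits[rung] = reaction_norm.fit_mixed(
            scores, reaction_norm.ModelSpec(fixed=fixed, random=rung)
        )
    rep = reaction_norm.adjusted_repeatability(fits["ri"], seed=cfg.seed)
    lrt_rows = []
    for a, b in (("ri", "rs1"), ("rs1", "rs2")):
        stat, df, p = reaction_norm.likelihood_ratio_test(fits[a], fits[b])
        lrt_rows.append({"null": a, "alt": b, "statistic": stat, "df": df, "p": p})
    pd.DataFrame(lrt_rows).to_csv(out / "lrt_ladder.csv", index=False)
    blups, corrs = reaction_norm.blup_summaries(fits["rs2"], seed=cfg.seed)
    blups.to_csv(out / "blups.csv", index=False)
    corrs.to_csv(out / "re_correlations_rs2.csv", index=False)
    ladder = []
    for rung, fit in fits.items():
        m, c = reaction_norm.r_squared(fit)
        ladder.append({"model": rung, "aic": fit.aic, "llf": fit.llf,
                       "marginal_r2": m, "conditional_r2": c,
                       "converged": fit.converged})
    pd.DataFrame(ladder).to_csv(out / "model_ladder.csv", index=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peak = reaction_norm.population_peak_day(fits["rs2"])
    report.update(
        repeatability=rep.point,
        repeatability_ci=[rep.lower95, rep.upper95],
        lrt=lrt_rows,
        peak_day=None if np.isnan(peak) else float(peak),
    )
    if not fits["ri"].converged:
        raise PipelineError("fit_rn", "RI model did not converge")


def _stage_fit_dhglm(cfg: RunConfig, out: Path, report: dict) -> None:
    scores = pd.read_csv(out / "scores.csv")
    fixed = tuple(
        c for c in reaction_norm.DEFAULT_FIXED if scores[c].nunique() > 1
    )
    spec = dispersion.DHGLMSpec(
        mean_fixed=fixed, n_chains=cfg.dhglm_chains, n_iter=cfg.dhglm_iter,
        seed=cfg.seed,
    )
    fit = dispersion.fit_dhglm(scores, spec)
    if not fit.converged:
        raise PipelineError(
            "fit_dhglm", f"chains not converged (max R-hat {fit.rhat_max:.3f})"
        )
    pred = dispersion.predictability_estimates(fit)
    pred.to_csv(out / "predictability.csv")
    cvp = dispersion.coefficient_of_variation_predictability(fit)
    report.update(cvp=cvp.point, cvp_ci=[cvp.lower95, cvp.upper95],
                  dhglm_rhat_max=fit.rhat_max)


def _stage_fit_welfare(cfg: RunConfig, out: Path, report: dict) -> None:
    scores = pd.read_csv(out / "scores.csv")
    wf = pd.read_csv(out / "welfare.csv")
    pred = pd.read_csv(out / "predictability.csv").set_index("hen_id")
    ntd = pd.read_csv(out / "no_transition_days.csv").set_index("hen_id")[
        "no_transition_days"
    ].fillna(0)
    fit = welfare.fit_bivariate(
        scores, wf, pred, ntd,
        n_iter=cfg.bivariate_iter, n_burn=cfg.bivariate_burn,
        thin=cfg.bivariate_thin, n_chains=cfg.bivariate_chains, seed=cfg.seed,
    )
    fe = welfare.fixed_effect_summary(fit)
    fe.to_csv(out / "welfare_fixed_effects.csv", index=False)
    rc = welfare.random_effect_correlations(fit)
    rc.to_csv(out / "welfare_re_correlations.csv", index=False)
    kbf = fe.set_index(["response", "term"])
    report.update(
        welfare_beta_predictability=float(
            kbf.loc[("kbf", "predictability"), "posterior_mean"]
        ),
        welfare_beta_ntd=float(
            kbf.loc[("kbf", "no_transition_days"), "posterior_mean"]
        ),
        welfare_correlations=rc.to_dict("records"),
        bivariate_rhat_max=fit.rhat_max,
    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the
    consolidated run report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    for stage in STAGES:
        if stage not in config.stages:
            report["stages"][stage] = "skipped"
            continue
        try:
            if stage == "simulate":
                _stage_simulate(config, out)
            elif stage == "features":
                _stage_features(config, out)
            elif stage == "score":
                _stage_score(config, out)
            elif stage == "fit_rn":
                _stage_fit_rn(config, out, report)
            elif stage == "fit_dhglm":
                _stage_fit_dhglm(config, out, report)
            elif stage == "fit_welfare":
                _stage_fit_welfare(config, out, report)
            report["stages"][stage] = "ok"
        except Exception as err:
            report["stages"][stage] = f"failed: {err}"
            report["failed_stage"] = stage
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=float)
            raise PipelineError(stage, str(err)) from err
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def acceptance_suite(seed: int = 1, reduced: bool = True) -> pd.DataFrame:
    """Run the calibrated recovery benchmarks and compare each recovered
    value with its generating truth at the stated tolerance."""
    from . import benchmarks

    # the reduced run keeps the full day span (the time range, not the hen
    # count, identifies the quadratic vertex) and halves the number of hens
    scale = dict(n_hens=40) if reduced else {}
    rows = []

    r = benchmarks.repeatability_recovery(seed, **scale)
    rows.append(("repeatability", r["value"], 0.44, 0.03 if not reduced else 0.08))
    r = benchmarks.peak_day_recovery(seed, **scale)
    rows.append(("peak_day", r["value"], 39.0, 2.0 if not reduced else 6.0))
    r = benchmarks.intercept_slope_corr_recovery(seed, **scale)
    rows.append(("intercept_slope_corr", r["value"], -0.79,
                 0.08 if not reduced else 0.15))
    df = pd.DataFrame(rows, columns=["target", "value", "truth", "tolerance"])
    df["pass"] = (df["value"] - df["truth"]).abs() <= df["tolerance"]
    return df
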