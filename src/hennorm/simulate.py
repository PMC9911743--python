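"""Synthetic study generator: hens, transition logs, daily movement scores
and end-of-lay welfare outcomes.

The generating process mirrors the study design: each hen carries a
4-vector of correlated random effects — intercept b0, linear time slope b1,
quadratic time slope b2 (its behavioural reaction norm) and a dispersion
intercept d on the log-residual-SD scale (its predictability).  Daily
movement scores follow

    y_it = beta·x_it + b0_i + b1_i·t + b2_i·t² + e_it,
    e_it ~ Normal(0, exp(log_sd0 + d_i)²),

with fixed effects of time, time², hatching treatment and daily outdoor
temperature.  Transition logs are generated by a continuous-time Markov
chain over the five aviary zones (exponential dwell times, jumps restricted
to physically adjacent zones), with a per-hen-day activity multiplier that
follows the hen's reaction norm and carries day-level noise scaled by
exp(d_i); during lights-off the hen remains in one sleeping zone.  On early days a hen may spend the entire day without a single
transition, parked on the top tier.  Welfare scores are a linear function
of per-hen predictability and the number of such no-transition days, plus a
laying-pen effect and residual noise, clipped to the 0–100 scoring scale.

Default parameter values reproduce, at the study's scale, the population
quantities the analysis estimates: an intercept-variance share of ~0.44, a
coefficient of variation in predictability of ~0.25, a population activity
peak near day 39, and ~34% of hens with at least one no-transition day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .barn import ZONE_ADJACENCY, ZONES, BarnCalendar

_R_DEFAULT = np.array(
    [
        [1.00, -0.69, 0.41, 0.00],
        [-0.69, 1.00, -0.89, 0.00],
        [0.41, -0.89, 1.00, 0.00],
        [0.00, 0.00, 0.00, 1.00],
    ]
)


class ConfigError(ValueError):
    pass


def _default_re_corr() -> np.ndarray:
    return _R_DEFAULT.copy()


@dataclass
class SimConfig:
    """Full parameterisation of the data-generating process.

    Scale conventions: the movement score is dimensionless (a PC1 score);
    time t is days post-transfer, uncentred, starting at 1; temperature is
    in °C and enters the score standardized; welfare scores are on the
    0–100 scale.
    """

    n_hens: int = 20
    n_days: int = 47
    n_pens: int = 8
    calendar: BarnCalendar | None = None
    # fixed effects on the movement score
    beta_time: float = 0.078
    beta_time2: float = -0.001
    beta_treatment: float = -0.5
    beta_temperature: float = -0.2
    # hen-level (co)variances: intercept, slope, slope², dispersion
    var_intercept: float = 1.0
    var_slope: float = 9e-4
    var_slope2: float = 2.5e-7
    var_dispersion: float = 0.0606
    re_correlations: np.ndarray = field(default_factory=_default_re_corr)
    resid_sd_baseline: float = 0.06  # log-scale intercept of the residual SD
    # welfare generating model (keel-bone-fracture severity)
    welfare_intercept: float = 36.0
    welfare_beta_pred: float = 23.54
    welfare_beta_ntd: float = 5.12
    welfare_pen_sd: float = 3.0
    welfare_resid_sd: float = 13.0
    # probability a hen spends one of days 1-3 without any transition
    p_no_transition_day: float = 0.13
    # when True, rescale the drawn hen effects so their sample covariance
    # equals the target exactly (mvrnorm empirical=TRUE); used by the
    # calibrated recovery benchmarks to remove finite-population noise
    empirical: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_hens < 2:
            raise ConfigError("n_hens must be >= 2")
        if self.n_days < 3:
            raise ConfigError("n_days must be >= 3")
        for name in ("var_intercept", "var_slope", "var_slope2", "var_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        R = np.asarray(self.re_correlations, dtype=float)
        if R.shape != (4, 4) or not np.allclose(R, R.T):
            raise ConfigError("re_correlations must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("re_correlations must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ConfigError("re_correlations must be positive-definite")
        self.re_correlations = R
        if self.calendar is None:
            self.calendar = BarnCalendar.regular(self.n_days)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class PopulationTruth:
    """Ground truth of one synthetic population, kept separate from the
    pipeline outputs so recovery tests never read truth through the pipeline."""

    hen_ids: np.ndarray          # (H,)
    effects: np.ndarray          # (H, 4): b0, b1, b2, d
    covariates: pd.DataFrame     # treatment, cls, pen, body_mass, tracked_days
    temperature: pd.Series       # °C, indexed by day
    true_repeatability: float
    true_cvp: float

    @property
    def b0(self) -> np.ndarray:
        return self.effects[:, 0]

    @property
    def d(self) -> np.ndarray:
        return self.effects[:, 3]

    def effects_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.effects, columns=["b0", "b1", "b2", "d"], index=self.hen_ids
        )
        return df.rename_axis("hen_id")


def make_population(config: SimConfig) -> PopulationTruth:
    """Draw per-hen random effects, covariates and the temperature series."""
    rng = np.random.default_rng(config.seed)
    H = config.n_hens
    sds = np.sqrt(
        [config.var_intercept, config.var_slope, config.var_slope2,
         config.var_dispersion]
    )
    L = np.linalg.cholesky(config.re_correlations)
    z = rng.standard_normal((H, 4))
    if config.empirical and H > int((sds > 0).sum()) + 1:
        # restandardise the active components so the realised sample moments
        # (mean 0, covariance = target at ddof=1) hold exactly
        active = np.flatnonzero(sds > 0)
        effects = np.zeros((H, 4))
        if active.size:
            za = z[:, active] - z[:, active].mean(axis=0)
            Ls = np.linalg.cholesky(np.atleast_2d(np.cov(za, rowvar=False)))
            Rt = config.re_correlations[np.ix_(active, active)]
            white = np.linalg.solve(Ls, za.T).T
            effects[:, active] = (white @ np.linalg.cholesky(Rt).T) * sds[active]
    else:
        effects = (z @ L.T) * sds  # zero rows where a variance is zero

    hen_ids = np.array([f"hen_{i:03d}" for i in range(H)])
    pens = np.arange(H) % config.n_pens
    treatment = (pens % 2).astype(int)  # pens alternate hatching treatment
    cls = rng.integers(0, 2, H)
    body_mass = rng.normal(1350.0, 90.0, H)  # grams at transfer
    tracked = np.full(H, config.n_days)

    cov = pd.DataFrame(
        {
            "hen_id": hen_ids,
            "treatment": treatment,
            "cls": cls,
            "pen": pens,
            "body_mass": body_mass,
            "tracked_days": tracked,
        }
    ).set_index("hen_id")

    days = np.arange(1, config.n_days + 1)
    temp = 12.0 + 6.0 * np.sin(2 * np.pi * days / 120.0) + rng.normal(0, 1.5, len(days))
    temperature = pd.Series(temp, index=days, name="temperature").rename_axis("day")

    mean_resid_var = float(
        np.exp(2 * config.resid_sd_baseline + 2 * config.var_dispersion)
    )
    denom = config.var_intercept + mean_resid_var
    true_r = config.var_intercept / denom if denom > 0 else float("nan")
    true_cvp = float(np.sqrt(np.expm1(config.var_dispersion)))
    return PopulationTruth(hen_ids, effects, cov, temperature, true_r, true_cvp)


def simulate_daily_scores(truth: PopulationTruth, config: SimConfig) -> pd.DataFrame:
    """Daily movement scores directly from the generating model (bypassing
    the transition-log route), in ScoreTable layout."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    days = np.arange(1, config.n_days + 1)
    ztemp = (truth.temperature - truth.temperature.mean()) / truth.temperature.std()
    H, T = len(truth.hen_ids), len(days)

    t = np.tile(days.astype(float), H)
    hen = np.repeat(truth.hen_ids, T)
    treat = np.repeat(truth.covariates["treatment"].to_numpy(), T)
    zt = np.tile(ztemp.to_numpy(), H)
    b = np.repeat(truth.effects, T, axis=0)
    mu = (
        config.beta_time * t
        + config.beta_time2 * t**2
        + config.beta_treatment * treat
        + config.beta_temperature * zt
        + b[:, 0]
        + b[:, 1] * t
        + b[:, 2] * t**2
    )
    sd = np.exp(config.resid_sd_baseline + b[:, 3])
    y = mu + rng.standard_normal(H * T) * sd

    df = pd.DataFrame(
        {
            "hen_id": hen,
            "day": np.tile(days, H),
            "pc1": y,
            "time": t,
            "time2": t**2,
            "treatment": treat,
            "temperature": zt,
        }
    )
    cov = truth.covariates[["cls", "pen", "body_mass", "tracked_days"]]
    df = df.merge(cov, left_on="hen_id", right_index=True, how="left")
    for c in ("body_mass", "tracked_days"):
        s = df[c].std()
        df[c] = (df[c] - df[c].mean()) / s if s > 0 else 0.0
    return df


# ---------------------------------------------------------------------------
# transition-log simulator (continuous-time Markov chain over zones)

#: baseline dwell rates (moves per hour) per zone during the lit period
_BASE_RATES = {
    "litter": 4.0,
    "lower_tier": 4.0,
    "nestbox_tier": 5.0,
    "top_tier": 2.5,
    "winter_garden": 5.0,
}
#: preference for sleeping zones (hens roost high)
_SLEEP_P = {"top_tier": 0.70, "nestbox_tier": 0.20, "lower_tier": 0.07, "litter": 0.03}


def simulate_transition_log(
    truth: PopulationTruth, config: SimConfig, return_dwell: bool = False
):
    """Simulate zone-entry records for every hen and tracked day.

    Dwell times in each zone are exponential with a zone-specific rate times
    a per-hen-day activity multiplier exp(0.3·eta/sd(b0) + eps), where eta is
    the hen's reaction-norm mean (fixed effects plus b0 + b1·t + b2·t²) and
    eps is day-level lognormal noise whose log-SD is 0.3·exp(d): hens with a
    larger dispersion effect d vary more from day to day, so the generating
    heterogeneity in predictability is expressed in the logs.  Jumps move
    only between physically adjacent zones.  The winter garden is reachable
    (from litter) only while open; at lights-off the hen settles into a
    sleeping zone until the next lights-on.  With probability
    ``p_no_transition_day`` a hen spends one of days 1–3 entirely on the top
    tier, without a single transition.

    When ``return_dwell`` is true, also returns the simulator's own per
    hen-day-zone dwell bookkeeping over the lit period (seconds), which the
    feature extractor must reproduce exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cal = config.calendar

    def epoch(dt):
        return pd.Timestamp(dt).value / 1e9

    sd_b0 = np.sqrt(config.var_intercept) if config.var_intercept > 0 else 1.0
    temp = truth.temperature
    ztemp = (temp - temp.mean()) / temp.std() if temp.std() > 0 else temp * 0.0
    treat_v = truth.covariates["treatment"].to_numpy(float)

    sleep_zones = list(_SLEEP_P)
    sleep_probs = np.array(list(_SLEEP_P.values()))
    adjacency = {z: list(a) for z, a in ZONE_ADJACENCY.items()}

    records = []  # (hen, epoch-seconds, zone)
    dwell_rows = []
    for h, hen in enumerate(truth.hen_ids):
        zone = "top_tier"  # placed on the top tier at transfer
        first = True
        for day in cal.day_indices:
            sched = cal[day]
            t_on = epoch(sched.lights_on)
            t_off = epoch(sched.lights_off)
            wg_open_t = epoch(sched.wg_open) if sched.wg_open else None

            day_no = day - cal.day_indices[0]
            if day_no < 3 and rng.random() < config.p_no_transition_day:
                # a full day parked on the top tier, no transitions
                if zone != "top_tier" or first:
                    records.append((hen, t_on, "top_tier"))
                zone = "top_tier"
                first = False
                if return_dwell:
                    occ = {z: 0.0 for z in ZONES}
                    occ["top_tier"] = t_off - t_on
                    dwell_rows.append({"hen_id": hen, "day": day, **occ})
                continue

            if first:
                records.append((hen, t_on, zone))
                first = False
            td = float(day)
            eta = (
                truth.effects[h, 0]
                + truth.effects[h, 1] * td
                + truth.effects[h, 2] * td**2
                + config.beta_time * td
                + config.beta_time2 * td**2
                + config.beta_treatment * treat_v[h]
                + config.beta_temperature * float(ztemp.get(day, 0.0))
            )
            eps = rng.normal(0.0, 0.3 * np.exp(truth.effects[h, 3]))
            mult = float(np.exp(0.3 * eta / sd_b0 + eps))
            occ = {z: 0.0 for z in ZONES}
            t = t_on
            while t < t_off:
                rate = _BASE_RATES[zone] * mult / 3600.0  # per second
                dt = rng.exponential(1.0 / rate)
                t_next = t + dt
                if t_next >= t_off:
                    occ[zone] += t_off - t
                    break
                occ[zone] += t_next - t
                t = t_next
                opts = [
                    z
                    for z in adjacency[zone]
                    if z != "winter_garden"
                    or (sched.wg_available and wg_open_t is not None and t >= wg_open_t)
                ]
                zone = opts[rng.integers(len(opts))] if opts else zone
                records.append((hen, t, zone))
            # night: settle into one sleeping zone until next lights-on;
            # the pop holes close at lights-off, so a hen still in the WG
            # is moved inside and sleeps on the litter
            night_zone = (
                "litter"
                if zone == "winter_garden"
                else sleep_zones[rng.choice(len(sleep_zones), p=sleep_probs)]
            )
            if night_zone != zone:
                zone = night_zone
                records.append((hen, t_off, zone))
            if return_dwell:
                dwell_rows.append({"hen_id": hen, "day": day, **occ})

    log = pd.DataFrame(records, columns=["hen_id", "timestamp", "zone"])
    log["timestamp"] = pd.to_datetime(log["timestamp"], unit="s")
    log = log.sort_values(["hen_id", "timestamp"], kind="stable").reset_index(drop=True)
    if return_dwell:
        return log, pd.DataFrame(dwell_rows)
    return log


def simulate_welfare(
    truth: PopulationTruth,
    config: SimConfig,
    predictability: pd.Series,
    ntd: pd.Series,
) -> pd.DataFrame:
    """End-of-lay welfare scores per hen, linearly linked to predictability
    and the no-transition-day count, clipped to the 0–100 scoring scale.

    The returned frame carries the fraction of clipped scores in
    ``.attrs['clipped_fraction']``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    missing = [h for h in truth.hen_ids if h not in predictability.index]
    if missing:
        raise KeyError(f"hens missing from predictability: {missing[:5]}")
    missing = [h for h in truth.hen_ids if h not in ntd.index]
    if missing:
        raise KeyError(f"hens missing from ntd: {missing[:5]}")

    pred = predictability.loc[truth.hen_ids].to_numpy(float)
    ntd_v = ntd.loc[truth.hen_ids].to_numpy(float)
    pens = truth.covariates["pen"].to_numpy()
    pen_eff = rng.normal(0.0, config.welfare_pen_sd, config.n_pens)
    raw = (
        config.welfare_intercept
        + config.welfare_beta_pred * pred
        + config.welfare_beta_ntd * ntd_v
        + pen_eff[pens]
        + rng.normal(0.0, config.welfare_resid_sd, len(pred))
    )
    kbf = np.clip(raw, 0.0, 100.0)
    feather_raw = 34.0 + pen_eff[pens] + rng.normal(0.0, 11.0, len(pred))
    feather = np.clip(feather_raw, 0.0, 100.0)
    out = pd.DataFrame(
        {"hen_id": truth.hen_ids, "kbf": kbf, "feather": feather, "pen": pens}
    )
    clipped = float(np.mean((raw != kbf) | (feather_raw != feather)))
    out.attrs["clipped_fraction"] = clipped
    return out
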