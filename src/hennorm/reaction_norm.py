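"""Behavioural reaction norms: the random-intercept / random-slope mixed
model cascade on the daily movement score.

Three nested Gaussian mixed models are fitted by REML with hen identity as
the grouping factor:

  RI   y_it = x'beta + b0_i + e_it
  RS1  adds a random linear time slope b1_i (correlated with b0_i)
  RS2  adds a random quadratic slope b2_i (full 3x3 covariance)

The ladder is compared with likelihood-ratio tests on the restricted
likelihood (identical fixed effects; no boundary correction, which makes
the tests conservative).  From the RI model we compute the adjusted
repeatability V_id / (V_id + V_res) with an interval obtained by simulating
variance-component vectors from the asymptotic normal approximation of
(log V_id, log V_res); per-hen effects are summarised by draws from their
conditional (BLUP) distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

RANDOM_LADDER = ("ri", "rs1", "rs2")
_RE_FORMULA = {"ri": "~1", "rs1": "~time", "rs2": "~time + time2"}
_RE_TERMS = {"ri": ["intercept"], "rs1": ["intercept", "slope"],
             "rs2": ["intercept", "slope", "slope2"]}

DEFAULT_FIXED = ("time", "time2", "treatment", "temperature")


@dataclass
class ModelSpec:
    """Which fixed effects enter and how rich the random part is."""

    fixed: tuple[str, ...] = DEFAULT_FIXED
    random: str = "ri"
    response: str = "pc1"
    group: str = "hen_id"

    def __post_init__(self):
        if self.random not in RANDOM_LADDER:
            raise ValueError(f"random part must be one of {RANDOM_LADDER}")
        if "time2" in self.fixed and "time" not in self.fixed:
            raise ValueError("time2 requires time among the fixed effects")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class IntervalEstimate:
    point: float
    lower95: float
    upper95: float
    n_draws: int

    def __post_init__(self):
        if not (self.lower95 <= self.point <= self.upper95):
            raise ValueError("interval must bracket the point estimate")


@dataclass
class MixedFit:
    spec: ModelSpec
    fe_params: pd.Series
    fe_se: pd.Series
    cov_re: pd.DataFrame          # hen-level covariance, response scale
    scale: float                  # residual variance V_res
    llf: float                    # restricted log-likelihood
    aic: float
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    re_modes: pd.DataFrame        # per-hen conditional modes, one col per term
    re_cond_cov: dict             # hen -> conditional covariance (ndarray)
    fitted: np.ndarray
    resid: np.ndarray
    data: pd.DataFrame = field(repr=False)

    @property
    def v_id(self) -> float:
        return float(self.cov_re.iloc[0, 0])

    @property
    def v_res(self) -> float:
        return float(self.scale)


def _fit_best(model):
    """Fit with the default optimizer, falling back to powell and cg when it
    fails to converge.  Candidates with a non-finite restricted likelihood
    (a degenerate optimum that some optimizers report as converged) are
    discarded; among the rest, converged fits win, then the higher llf."""
    cands = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cands.append(model.fit(reml=True, maxiter=500))
        except Exception:
            pass
        first_ok = (
            cands and cands[0].converged and np.isfinite(cands[0].llf)
        )
        if not first_ok:
            for method in ("powell", "cg"):
                try:
                    cands.append(model.fit(reml=True, method=method, maxiter=2000))
                except Exception:
                    pass
    valid = [r for r in cands if np.isfinite(r.llf)]
    pool = valid or cands
    if not pool:
        raise RuntimeError("all mixed-model optimizers failed")
    pool.sort(key=lambda r: (bool(r.converged), float(r.llf)))
    return pool[-1]


def fit_mixed(scores: pd.DataFrame, spec: ModelSpec) -> MixedFit:
    """Fit one rung of the RI/RS1/RS2 ladder by REML."""
    data = scores.dropna(subset=[spec.response]).copy()
    if not np.isfinite(data[spec.response]).all():
        raise ValueError("non-finite response values")
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 hens")
    model = smf.mixedlm(
        spec.formula, data, groups=data[spec.group], re_formula=_RE_FORMULA[spec.random]
    )
    res = _fit_best(model)

    terms = _RE_TERMS[spec.random]
    cov_re = pd.DataFrame(
        np.asarray(res.cov_re, float), index=terms, columns=terms
    )
    # boundary: a hen-level variance collapsed (relative to residual) or the
    # random-effect correlation matrix is numerically singular
    diag = np.diag(cov_re.to_numpy())
    boundary = bool(np.any(diag < 1e-8 * res.scale))
    if not boundary and len(terms) > 1:
        dd = np.sqrt(np.outer(diag, diag))
        corr = cov_re.to_numpy() / np.where(dd > 0, dd, 1.0)
        boundary = bool(np.linalg.eigvalsh(corr).min() < 1e-6)

    k = len(res.fe_params) + model.k_re2 + model.k_vc + 1  # +1: residual var
    group_labels = list(pd.unique(data[spec.group]))
    try:
        modes = pd.DataFrame(res.random_effects).T
        modes.columns = terms
        cond_cov = {
            g: np.asarray(c, float) for g, c in res.random_effects_cov.items()
        }
    except (np.linalg.LinAlgError, ValueError):
        # a variance at the boundary makes the RE covariance singular; the
        # conditional modes collapse to zero with zero conditional spread
        boundary = True
        modes = pd.DataFrame(
            np.zeros((len(group_labels), len(terms))),
            index=group_labels, columns=terms,
        )
        cond_cov = {g: np.zeros((len(terms), len(terms))) for g in group_labels}
    modes = modes.rename_axis("hen_id")
    Z = np.ones((len(data), len(terms)))
    if "slope" in terms:
        Z[:, terms.index("slope")] = data["time"].to_numpy(float)
    if "slope2" in terms:
        Z[:, terms.index("slope2")] = data["time2"].to_numpy(float)
    re_rows = modes.loc[data[spec.group]].to_numpy()
    fitted = model.exog @ np.asarray(res.fe_params, float) + (Z * re_rows).sum(axis=1)
    resid = data[spec.response].to_numpy(float) - fitted
    return MixedFit(
        spec=spec,
        fe_params=res.fe_params,
        fe_se=res.bse_fe,
        cov_re=cov_re,
        scale=float(res.scale),
        llf=float(res.llf),
        aic=float(-2 * res.llf + 2 * k),
        converged=bool(res.converged),
        boundary=boundary,
        n_obs=int(model.nobs),
        n_groups=int(model.n_groups),
        re_modes=modes,
        re_cond_cov=cond_cov,
        fitted=fitted,
        resid=resid,
        data=data,
    )


_LRT_DF = {("ri", "rs1"): 2, ("rs1", "rs2"): 3, ("ri", "rs2"): 5}


def likelihood_ratio_test(m0: MixedFit, m1: MixedFit):
    """LRT between nested rungs of the random-effect ladder (REML; identical
    fixed effects required).  No boundary correction is applied, so the test
    is conservative for variance components."""
    key = (m0.spec.random, m1.spec.random)
    if key not in _LRT_DF:
        raise ValueError(f"models not nested in the ladder: {key}")
    if tuple(m0.spec.fixed) != tuple(m1.spec.fixed):
        raise ValueError("LRT on the restricted likelihood requires identical "
                         "fixed effects")
    if m0.n_obs != m1.n_obs:
        raise ValueError("models fitted to different data")
    stat = max(0.0, 2.0 * (m1.llf - m0.llf))
    df = _LRT_DF[key]
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# closed-form RI REML log-likelihood (used for the repeatability interval)


def _ri_reml_loglike(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                     v_id: float, v_res: float) -> float:
    """Restricted log-likelihood of the random-intercept model, evaluated
    directly via the compound-symmetry Woodbury identity (independent of the
    statsmodels fitting path)."""
    n, p = X.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for g in np.unique(groups):
        m = groups == g
        Xi, yi = X[m], y[m]
        ni = int(m.sum())
        a = v_id / (v_res * (v_res + ni * v_id))
        sx, sy = Xi.sum(axis=0), yi.sum()
        xtvx += Xi.T @ Xi / v_res - a * np.outer(sx, sx)
        xtvy += Xi.T @ yi / v_res - a * sx * sy
        ytvy += yi @ yi / v_res - a * sy * sy
        logdet += (ni - 1) * np.log(v_res) + np.log(v_res + ni * v_id)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    sign, logdet_x = np.linalg.slogdet(xtvx)
    return -0.5 * (logdet + logdet_x + quad + (n - p) * np.log(2 * np.pi))


def adjusted_repeatability(
    fit: MixedFit, n_draws: int = 1000, seed: int | None = 0
) -> IntervalEstimate:
    """Adjusted repeatability V_id/(V_id+V_res) from the RI model, with a 95%
    interval from ``n_draws`` simulated variance-component vectors.

    The vectors are drawn from the asymptotic normal approximation of
    (log V_id, log V_res) at the REML optimum, with curvature taken from a
    numerically differentiated closed-form RI restricted likelihood.
    """
    if fit.spec.random != "ri":
        raise ValueError("repeatability is defined on the RI model")
    v_id, v_res = fit.v_id, fit.v_res
    if v_id + v_res <= 0:
        raise ValueError("total variance is zero; repeatability undefined")
    point = v_id / (v_id + v_res)

    y = fit.data[fit.spec.response].to_numpy(float)
    import patsy

    X = np.asarray(patsy.dmatrix(
        " + ".join(fit.spec.fixed) if fit.spec.fixed else "1", fit.data
    ), float)
    groups = fit.data[fit.spec.group].to_numpy()

    v_id_f = max(v_id, 1e-8 * v_res)  # keep the log-scale finite at boundary
    theta = np.log([v_id_f, v_res])

    def nll(th):
        return -_ri_reml_loglike(y, X, groups, np.exp(th[0]), np.exp(th[1]))

    h = 1e-4
    H = np.zeros((2, 2))
    f0 = nll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        # guard against a non-PD Hessian at a boundary optimum
        ev = np.linalg.eigvalsh(cov)
        if ev.min() <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.diag([4.0 / max(fit.n_groups, 1), 2.0 / max(fit.n_obs, 1)])
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta, cov, size=n_draws)
    v = np.exp(draws)
    ratios = v[:, 0] / (v[:, 0] + v[:, 1])
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return IntervalEstimate(
        point=float(point),
        lower95=float(min(lo, point)),
        upper95=float(max(hi, point)),
        n_draws=n_draws,
    )


def blup_summaries(fit: MixedFit, n_draws: int = 1000, seed: int | None = 0):
    """Per-hen random-effect summaries (mean ± SD over draws from the
    conditional BLUP distribution) and the estimated random-effect
    correlations.

    Returns ``(per_hen, correlations)``; a singular conditional covariance is
    handled with its eigenvalue-floored pseudo-root and flagged in the
    ``pseudo`` column.
    """
    rng = np.random.default_rng(seed)
    terms = list(fit.re_modes.columns)
    rows = []
    for hen, mode in fit.re_modes.iterrows():
        C = fit.re_cond_cov[hen]
        ev, U = np.linalg.eigh(np.atleast_2d(C))
        pseudo = bool(ev.min() < 0)
        root = U * np.sqrt(np.clip(ev, 0, None))
        draws = mode.to_numpy() + rng.standard_normal((n_draws, len(terms))) @ root.T
        for k, term in enumerate(terms):
            rows.append(
                {
                    "hen_id": hen,
                    "term": term,
                    "mean": float(draws[:, k].mean()),
                    "sd": float(draws[:, k].std(ddof=1)),
                    "pseudo": pseudo,
                }
            )
    per_hen = pd.DataFrame(rows)

    cov = fit.cov_re.to_numpy()
    sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    denom = np.outer(sd, sd)
    corr = np.divide(cov, denom, out=np.full_like(cov, np.nan), where=denom > 0)
    crows = [
        {"term_a": terms[i], "term_b": terms[j], "correlation": float(corr[i, j])}
        for i in range(len(terms))
        for j in range(i + 1, len(terms))
    ]
    return per_hen, pd.DataFrame(crows)


def r_squared(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R² (variance explained by fixed effects
    alone, and by fixed plus random effects), using the mean-covariate
    formulation for the random-slope variance contribution."""
    import patsy

    X = np.asarray(patsy.dmatrix(
        " + ".join(fit.spec.fixed) if fit.spec.fixed else "1", fit.data
    ), float)
    var_f = float(np.var(X @ fit.fe_params.to_numpy()))
    terms = list(fit.cov_re.columns)
    Z = np.ones((len(fit.data), len(terms)))
    if "slope" in terms:
        Z[:, terms.index("slope")] = fit.data["time"].to_numpy(float)
    if "slope2" in terms:
        Z[:, terms.index("slope2")] = fit.data["time2"].to_numpy(float)
    S = fit.cov_re.to_numpy()
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, S, Z)))
    total = var_f + var_r + fit.scale
    return var_f / total, (var_f + var_r) / total


def population_peak_day(fit: MixedFit) -> float:
    """Day post-transfer at which the population-level quadratic time trend
    peaks: -beta_time / (2 beta_time2).  Returns NaN (with a warning) when
    the quadratic coefficient is non-negative (no interior maximum)."""
    if "time" not in fit.fe_params.index or "time2" not in fit.fe_params.index:
        raise ValueError("fit must include time and time2 fixed effects")
    b1 = float(fit.fe_params["time"])
    b2 = float(fit.fe_params["time2"])
    if b1 == 0:
        return 0.0
    if b2 >= 0:
        warnings.warn("non-negative quadratic term: no interior maximum")
        return float("nan")
    return -b1 / (2.0 * b2)
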