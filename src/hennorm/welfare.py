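"""Bivariate Bayesian model linking daily movement scores to a single
end-of-lay welfare score per hen.

Responses: the repeated daily movement score y_it and one welfare score k_i
(keel-bone-fracture severity or feather damage, 0–100).  Hen-level random
effects are a joint 4-vector (movement intercept, linear slope, quadratic
slope, welfare deviation) with an unstructured covariance G2; laying pen
enters as a random effect on the welfare response.  Because the welfare
score has no repeated measures, its residual variance is not estimable and
is pinned at a small constant (1e-4) with zero residual covariance between
the responses; the hen-level welfare deviation then plays the residual's
role, and the hen-level covariance carries the associations between welfare
and the movement reaction-norm components.

Sampling is a conjugate Gibbs scheme.  The near-zero welfare residual makes
the welfare fixed effects almost collinear with the hen welfare deviations,
so the welfare-side location block (fixed effects, pen effects, hen welfare
deviations) is drawn by composition with the hen deviation integrated out
of the first two conditionals — equivalent to a joint block update, which
restores mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

RE_TERMS = ("intercept", "slope", "slope2", "welfare")

MOVEMENT_FIXED = ("time", "time2", "treatment", "temperature")
WELFARE_FIXED = ("predictability", "no_transition_days", "treatment", "cls",
                 "body_mass")


def load_welfare_table(path, complement_feather: bool = False) -> pd.DataFrame:
    """Read a welfare table (hen_id, kbf, feather, pen).  With
    ``complement_feather`` the feather column is replaced by its complement
    to 100, so that higher values mean poorer plumage."""
    df = pd.read_csv(path)
    need = {"hen_id", "kbf", "feather", "pen"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"welfare table missing columns: {sorted(missing)}")
    if df["hen_id"].duplicated().any():
        raise ValueError("welfare scores must be one row per hen")
    for c in ("kbf", "feather"):
        if ((df[c] < 0) | (df[c] > 100)).any():
            raise ValueError(f"{c} scores must lie in [0, 100]")
    if complement_feather:
        df = df.assign(feather=100.0 - df["feather"])
    return df


@dataclass
class BivariatePriors:
    """Prior structure: residual scale diag(1, 1e-4) with belief 1.002 and
    the welfare entry fixed (not sampled); hen-level G scale I with belief
    equal to its dimension; pen-level scale 1 with belief 1; effectively
    flat normal priors on fixed effects."""

    resid_scale_movement: float = 1.0
    resid_nu: float = 1.002
    welfare_resid_var: float = 1e-4
    g2_scale: np.ndarray = field(default_factory=lambda: np.eye(4))
    g2_nu: float = 4.0
    g1_scale: float = 1.0
    g1_nu: float = 1.0
    fixed_var: float = 1e8


@dataclass
class BivariateFit:
    response: str
    movement_fixed: list[str]
    welfare_fixed: list[str]
    hen_ids: np.ndarray
    pen_ids: np.ndarray
    draws: dict                  # (chains, draws, ...) arrays
    welfare_resid_var: float
    converged: bool
    rhat_max: float

    def g2_correlation_draws(self) -> np.ndarray:
        G = self.draws["G2"]
        sd = np.sqrt(np.einsum("...ii->...i", G))
        return G / (sd[..., :, None] * sd[..., None, :])


def fit_bivariate(
    scores: pd.DataFrame,
    welfare: pd.DataFrame,
    predictability: pd.DataFrame,
    ntd: pd.Series,
    priors: BivariatePriors | None = None,
    response: str = "kbf",
    n_iter: int = 20_000,
    n_burn: int = 4_000,
    thin: int = 10,
    n_chains: int = 3,
    seed: int = 0,
    rhat_threshold: float = 1.05,
) -> BivariateFit:
    """Fit the bivariate movement + welfare model by MCMC.

    ``scores`` is the ScoreTable (repeated hen-days); ``welfare`` has one
    row per hen; ``predictability`` is the DHGLM output (indexed by hen);
    ``ntd`` the per-hen no-transition-day counts.
    """
    priors = priors or BivariatePriors()
    df = scores.dropna(subset=["pc1"]).copy()
    hen_ids, hen_idx = np.unique(df["hen_id"].to_numpy(), return_inverse=True)
    wf = welfare.set_index("hen_id") if "hen_id" in welfare.columns else welfare
    missing = [h for h in hen_ids if h not in wf.index]
    if missing:
        raise KeyError(f"hens missing from welfare table: {missing[:5]}")
    wf = wf.loc[hen_ids]
    if response not in wf.columns:
        raise ValueError(f"unknown welfare response {response!r}")

    y = df["pc1"].to_numpy(float)
    t = df["time"].to_numpy(float)
    Z = np.column_stack([np.ones_like(t), t, t * t])
    Xm = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in MOVEMENT_FIXED]
    )
    m_names = ["intercept"] + list(MOVEMENT_FIXED)

    # welfare design: predictability + ntd + hen covariates (mass standardized)
    pred = predictability["predictability"].reindex(hen_ids)
    if pred.isna().any():
        raise KeyError("hens missing from predictability table")
    ntd_v = pd.Series(ntd).reindex(hen_ids)
    if ntd_v.isna().any():
        raise KeyError("hens missing from no-transition-day counts")
    hen_cov = df.groupby("hen_id")[["treatment", "cls", "body_mass"]].first()
    hen_cov = hen_cov.reindex(hen_ids)
    bm = hen_cov["body_mass"].to_numpy(float)
    if bm.std() > 0:
        bm = (bm - bm.mean()) / bm.std()
    Xw = np.column_stack(
        [
            np.ones(len(hen_ids)),
            pred.to_numpy(float),
            ntd_v.to_numpy(float),
            hen_cov["treatment"].to_numpy(float),
            hen_cov["cls"].to_numpy(float),
            bm,
        ]
    )
    w_names = ["intercept"] + list(WELFARE_FIXED)
    k = wf[response].to_numpy(float)
    pen_ids, pen_idx = np.unique(wf["pen"].to_numpy(), return_inverse=True)

    H, P = len(hen_ids), len(pen_ids)
    pm, pw = Xm.shape[1], Xw.shape[1]
    n_keep = (n_iter - n_burn) // thin

    # per-hen sufficient statistics for the movement side (constant)
    ZZ = np.zeros((H, 3, 3))
    np.add.at(ZZ, hen_idx, Z[:, :, None] * Z[:, None, :])
    Zy = np.zeros((H, 3))
    np.add.at(Zy, hen_idx, Z * y[:, None])
    ZX = np.zeros((H, 3, pm))
    np.add.at(ZX, hen_idx, Z[:, :, None] * Xm[:, None, :])
    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    XwtXw = Xw.T @ Xw

    v_eps = priors.welfare_resid_var
    from .dispersion import _hen_constant

    # likelihood-invariant shift directions: Xm columns 0..2 coincide with Z,
    # and hen-constant covariates are compensated by the hen intercept
    shift_pairs = [(c, c, np.ones(H)) for c in range(3)]
    for j in range(3, pm):
        w = _hen_constant(Xm[:, j], hen_idx, H)
        if w is not None and np.any(w != 0):
            shift_pairs.append((0, j, w))
    chain_out = {kk: [] for kk in ("beta_m", "beta_w", "G2", "g1", "sigma_m2",
                                   "a", "p")}
    root = np.random.SeedSequence([seed, 211])
    for ss in root.spawn(n_chains):
        rng = np.random.default_rng(ss)
        res = _run_bivariate_chain(
            y, k, Xm, Xw, Z, hen_idx, pen_idx, ZZ, Zy, ZX, XtX, Xty, XwtXw,
            H, P, pm, pw, shift_pairs, priors, n_iter, n_burn, thin, n_keep,
            rng
        )
        for kk in chain_out:
            chain_out[kk].append(res[kk])
    draws = {kk: np.stack(v) for kk, v in chain_out.items()}

    rhat_max = float("nan")
    converged = True
    if n_chains >= 2:
        pop = {
            "beta_m": draws["beta_m"],
            "beta_w": draws["beta_w"],
            "G2_diag": np.einsum("csii->csi", draws["G2"]),
            "sigma_m2": draws["sigma_m2"],
        }
        rh = az.rhat(az.convert_to_dataset(pop))
        rhat_max = float(
            max(np.nanmax(np.atleast_1d(rh[v].values)) for v in rh.data_vars)
        )
        converged = bool(rhat_max <= rhat_threshold)
        if not converged:
            warnings.warn(f"bivariate chains not converged (max R-hat "
                          f"{rhat_max:.3f})")
    # lag-1 autocorrelation of the thinned chains
    for name in ("beta_m", "beta_w"):
        arr = draws[name]
        a0 = arr - arr.mean(axis=1, keepdims=True)
        num = (a0[:, 1:] * a0[:, :-1]).sum(axis=1)
        den = (a0**2).sum(axis=1)
        ac = np.abs(num / np.where(den > 0, den, 1.0))
        if np.nanmax(ac) > 0.05:
            warnings.warn(
                f"lag-1 autocorrelation after thinning exceeds 0.05 for "
                f"{name} (max {np.nanmax(ac):.2f}); consider a higher "
                "thinning rate"
            )
    return BivariateFit(
        response=response,
        movement_fixed=m_names,
        welfare_fixed=w_names,
        hen_ids=hen_ids,
        pen_ids=pen_ids,
        draws=draws,
        welfare_resid_var=v_eps,
        converged=converged,
        rhat_max=rhat_max,
    )


def _run_bivariate_chain(y, k, Xm, Xw, Z, hen_idx, pen_idx, ZZ, Zy, ZX, XtX,
                         Xty, XwtXw, H, P, pm, pw, shift_pairs, priors,
                         n_iter, n_burn, thin, n_keep, rng):
    v_eps = priors.welfare_resid_var
    n_m = len(y)
    # overdispersed starting values
    beta_m = np.linalg.lstsq(Xm, y, rcond=None)[0] + rng.normal(0, 0.5, pm)
    beta_w = np.linalg.lstsq(Xw, k, rcond=None)[0] + rng.normal(0, 2.0, pw)
    a = np.zeros((H, 4))
    a[:, 3] = k - Xw @ beta_w
    p_eff = np.zeros(P)
    sigma_m2 = max(np.var(y - Xm @ beta_m), 1e-3) * rng.uniform(0.5, 2.0)
    g1 = priors.g1_scale * rng.uniform(0.5, 2.0)
    G2 = np.eye(4)
    G2[3, 3] = max(np.var(a[:, 3]), 1.0)

    fixed_prec = 1.0 / priors.fixed_var
    kept = {
        "beta_m": np.empty((n_keep, pm)),
        "beta_w": np.empty((n_keep, pw)),
        "G2": np.empty((n_keep, 4, 4)),
        "g1": np.empty(n_keep),
        "sigma_m2": np.empty(n_keep),
        "a": np.empty((n_keep, H, 4)),
        "p": np.empty((n_keep, P)),
    }
    j_out = 0
    for it in range(n_iter):
        # ---- movement fixed effects (conjugate) ----
        A = XtX / sigma_m2 + fixed_prec * np.eye(pm)
        b = (Xty - np.einsum("hkp,hk->p", ZX, a[:, :3])) / sigma_m2
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, b)
        beta_m = mu + np.linalg.solve(L.T, rng.standard_normal(pm))

        # ---- welfare location block (hen deviation collapsed) ----
        G11 = G2[:3, :3]
        g12 = G2[:3, 3]
        cvec = np.linalg.solve(G11, g12)
        m_aw = a[:, :3] @ cvec                      # E[aw | a0:2]
        s2_aw = max(G2[3, 3] - g12 @ cvec, 1e-10)   # var[aw | a0:2]
        v_marg = s2_aw + v_eps
        # beta_w with aw integrated out
        r = k - p_eff[pen_idx] - m_aw
        A = XwtXw / v_marg + fixed_prec * np.eye(pw)
        b = Xw.T @ r / v_marg
        L = np.linalg.cholesky(A)
        beta_w = np.linalg.solve(A, b) + np.linalg.solve(
            L.T, rng.standard_normal(pw)
        )
        # pen effects with aw integrated out
        r = k - Xw @ beta_w - m_aw
        n_pen = np.bincount(pen_idx, minlength=P).astype(float)
        prec = n_pen / v_marg + 1.0 / g1
        mean = np.bincount(pen_idx, r, minlength=P) / v_marg / prec
        p_eff = mean + rng.standard_normal(P) / np.sqrt(prec)

        # ---- hen-level 4-vectors (joint conjugate, batched) ----
        G2inv = np.linalg.inv(G2)
        Pmat = np.broadcast_to(G2inv, (H, 4, 4)).copy()
        Pmat[:, :3, :3] += ZZ / sigma_m2
        Pmat[:, 3, 3] += 1.0 / v_eps
        rhs = np.zeros((H, 4))
        rhs[:, :3] = (Zy - ZX @ beta_m) / sigma_m2
        rhs[:, 3] = (k - Xw @ beta_w - p_eff[pen_idx]) / v_eps
        Lb = np.linalg.cholesky(Pmat)
        mu = np.linalg.solve(Pmat, rhs[:, :, None])[:, :, 0]
        z = rng.standard_normal((H, 4))
        a = mu + np.linalg.solve(np.swapaxes(Lb, 1, 2), z[:, :, None])[:, :, 0]

        # ---- exact location shifts along likelihood-invariant directions:
        # Xm columns 0..2 (intercept, time, time2) coincide with the Z
        # columns, and the pen effects share the welfare intercept ----
        G2inv = np.linalg.inv(G2)
        for c, j, w in shift_pairs:
            prec = (w @ w) * G2inv[c, c] + fixed_prec
            mean = ((a @ G2inv[c]) @ w - fixed_prec * beta_m[j]) / prec
            delta = mean + rng.standard_normal() / np.sqrt(prec)
            beta_m[j] += delta
            a[:, c] -= delta * w
        prec = P / g1 + fixed_prec
        mean = (p_eff.sum() / g1 - fixed_prec * beta_w[0]) / prec
        delta = mean + rng.standard_normal() / np.sqrt(prec)
        beta_w[0] += delta
        p_eff = p_eff - delta

        # ---- variance components ----
        resid_m = y - Xm @ beta_m - np.einsum("nk,nk->n", Z, a[hen_idx, :3])
        ssr = resid_m @ resid_m
        nu_post = priors.resid_nu + n_m
        sigma_m2 = (
            priors.resid_nu * priors.resid_scale_movement + ssr
        ) / rng.chisquare(nu_post)
        g1 = (priors.g1_nu * priors.g1_scale + p_eff @ p_eff) / rng.chisquare(
            priors.g1_nu + P
        )
        G2 = stats.invwishart.rvs(
            df=priors.g2_nu + H,
            scale=priors.g2_scale + a.T @ a,
            random_state=rng,
        )

        if it >= n_burn and (it - n_burn) % thin == 0 and j_out < n_keep:
            kept["beta_m"][j_out] = beta_m
            kept["beta_w"][j_out] = beta_w
            kept["G2"][j_out] = G2
            kept["g1"][j_out] = g1
            kept["sigma_m2"][j_out] = sigma_m2
            kept["a"][j_out] = a
            kept["p"][j_out] = p_eff
            j_out += 1
    return {kk: v[:j_out] for kk, v in kept.items()}


def random_effect_correlations(fit: BivariateFit) -> pd.DataFrame:
    """Posterior summaries of the hen-level correlations between the welfare
    deviation and each movement reaction-norm component (plus the movement
    components among themselves); significant = 95% CI excludes 0."""
    corr = fit.g2_correlation_draws().reshape(-1, 4, 4)
    ok = np.isfinite(corr).all(axis=(1, 2))
    n_rejected = int((~ok).sum())
    corr = corr[ok]
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            cs = corr[:, i, j]
            lo, hi = np.percentile(cs, [2.5, 97.5])
            rows.append(
                {
                    "term_a": RE_TERMS[i],
                    "term_b": RE_TERMS[j],
                    "posterior_mean": float(cs.mean()),
                    "lower95": float(lo),
                    "upper95": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_rejected_draws"] = n_rejected
    return out


def fixed_effect_summary(fit: BivariateFit) -> pd.DataFrame:
    """Posterior mean, 95% CI and significance flag for every fixed effect
    of both responses."""
    rows = []
    for resp, key, names in (
        ("movement", "beta_m", fit.movement_fixed),
        (fit.response, "beta_w", fit.welfare_fixed),
    ):
        arr = fit.draws[key].reshape(-1, len(names))
        for j, nm in enumerate(names):
            cs = arr[:, j]
            lo, hi = np.percentile(cs, [2.5, 97.5])
            rows.append(
                {
                    "response": resp,
                    "term": nm,
                    "posterior_mean": float(cs.mean()),
                    "lower95": float(lo),
                    "upper95": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)
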