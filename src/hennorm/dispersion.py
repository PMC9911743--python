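"""Double-hierarchical Gaussian model (DHGLM): hen-level effects in both the
mean and the residual-dispersion part of the daily movement score.

    y_it ~ Normal(mu_it, sigma_it²)
    mu_it      = x' beta + b0_i + b1_i t + b2_i t²
    log sigma_it = w' gamma + d_i
    (b0, b1, b2, d)_i ~ MVN(0, Sigma)            (4x4 hen-level covariance)

d_i is the hen's dispersion intercept; its sign-flipped posterior mean is
the hen's *predictability* (higher = smaller residual SD).  The population
spread of predictability is summarised by CVp = sqrt(exp(V_d) - 1), the
coefficient of variation of the hen residual SDs implied by the lognormal
distribution with among-hen log-scale variance V_d = Sigma[d,d].

Sampling is Metropolis-within-Gibbs: conjugate normal updates for the fixed
effects and the mean-part hen effects, adaptive random-walk Metropolis for
the dispersion fixed effects and each d_i (whose 1-D conditional target has
sufficient statistics n_i and the weighted residual sum of squares), and a
conjugate inverse-Wishart update for Sigma.  Priors are weakly informative:
Normal(0, 10²) on fixed effects, inverse-Wishart(dim+2, 0.01·I) on Sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .reaction_norm import DEFAULT_FIXED, IntervalEstimate

RE_TERMS = ("intercept", "slope", "slope2", "dispersion")


@dataclass
class DHGLMSpec:
    """Model structure and MCMC settings.

    ``n_iter`` counts total iterations per chain, of which the first
    ``n_burn`` (default half) are discarded and used for step-size
    adaptation.  The study-scale run (10 chains x 50,000, 25,000 burn-in,
    thinning 3) is reached by raising these settings.
    """

    mean_fixed: tuple[str, ...] = DEFAULT_FIXED
    disp_fixed: tuple[str, ...] = ()  # dispersion covariates beyond intercept
    mean_random: tuple[str, ...] = ("intercept", "slope", "slope2")
    include_dispersion_random: bool = True
    n_chains: int = 4
    n_iter: int = 2000
    n_burn: int | None = None
    thin: int = 1
    seed: int = 0
    prior_beta_sd: float = 10.0
    prior_gamma_sd: float = 10.0
    prior_sigma_df: float = 6.0
    prior_sigma_scale: float = 0.01
    rhat_threshold: float = 1.05
    store_loglik: bool = True

    def __post_init__(self):
        allowed = RE_TERMS[:3]
        if (not self.mean_random or "intercept" not in self.mean_random
                or any(t not in allowed for t in self.mean_random)):
            raise ValueError(
                f"mean_random must be a subset of {allowed} containing "
                "'intercept'"
            )
        if self.n_chains < 2:
            warnings.warn("fewer than 2 chains: R-hat will be unavailable")
        if self.n_burn is None:
            self.n_burn = self.n_iter // 2
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")


@dataclass
class DHGLMFit:
    spec: DHGLMSpec
    hen_ids: np.ndarray
    mean_fixed_names: list[str]
    disp_fixed_names: list[str]
    draws: dict            # name -> (chains, draws, ...) arrays
    loglik: np.ndarray | None  # (chains, draws_ll, n_obs)
    y: np.ndarray
    converged: bool
    rhat_max: float
    accept_d: float
    accept_gamma: float

    @property
    def re_positions(self) -> list[int]:
        """Indices into RE_TERMS of the active random effects (Sigma draws
        are stored zero-padded to 4x4 in this ordering)."""
        pos = [RE_TERMS.index(t) for t in self.spec.mean_random]
        if self.spec.include_dispersion_random:
            pos.append(3)
        return pos

    @property
    def n_random_terms(self) -> int:
        return len(self.re_positions)

    def v_d_draws(self) -> np.ndarray:
        if not self.spec.include_dispersion_random:
            raise ValueError("model has no dispersion random effect")
        return self.draws["Sigma"][..., 3, 3]

    def re_correlation_draws(self) -> np.ndarray:
        pos = self.re_positions
        S = self.draws["Sigma"][..., pos, :][..., :, pos]
        sd = np.sqrt(np.einsum("...ii->...i", S))
        return S / (sd[..., :, None] * sd[..., None, :])


def _design(scores: pd.DataFrame, fixed: tuple[str, ...]):
    X = np.ones((len(scores), 1 + len(fixed)))
    for k, name in enumerate(fixed):
        X[:, 1 + k] = scores[name].to_numpy(float)
    return X, ["intercept"] + list(fixed)


def _batched_mvn_sample(P, b, rng):
    """Draw from N(P^-1 b, P^-1) for a batch of small precision matrices."""
    L = np.linalg.cholesky(P)
    mu = np.linalg.solve(P, b[..., None])[..., 0]
    z = rng.standard_normal(b.shape)
    Lt = np.swapaxes(L, -1, -2)
    return mu + np.linalg.solve(Lt, z[..., None])[..., 0]


def fit_dhglm(scores: pd.DataFrame, spec: DHGLMSpec) -> DHGLMFit:
    """Fit the DHGLM by MCMC.  Returns the fit with a convergence flag set
    from split-R-hat on the population-level parameters (never raises on
    non-convergence; downstream stages check ``converged``)."""
    df = scores.dropna(subset=["pc1"]).copy()
    y = df["pc1"].to_numpy(float)
    X, mean_names = _design(df, spec.mean_fixed)
    W, disp_names = _design(df, spec.disp_fixed)
    hen_ids, hen_idx = np.unique(df["hen_id"].to_numpy(), return_inverse=True)
    t = df["time"].to_numpy(float)
    re_pos = [RE_TERMS.index(term) for term in spec.mean_random]
    Z = np.column_stack([np.ones_like(t), t, t * t])[:, re_pos]
    H, n, p, q = len(hen_ids), len(y), X.shape[1], W.shape[1]
    n_i = np.bincount(hen_idx, minlength=H).astype(float)
    k = Z.shape[1]
    dim = k + 1 if spec.include_dispersion_random else k
    pos4 = re_pos + ([3] if spec.include_dispersion_random else [])

    n_keep = (spec.n_iter - spec.n_burn) // spec.thin
    ll_thin = max(1, n_keep // 250) if spec.store_loglik else None

    shift_pairs = _location_shift_pairs(X, Z, hen_idx, H, spec)

    chains = {k: [] for k in ("beta", "gamma", "u", "d", "Sigma")}
    ll_chains = []
    acc_d_all, acc_g_all = [], []
    root = np.random.SeedSequence([spec.seed, 97])
    for chain, ss in enumerate(root.spawn(spec.n_chains)):
        rng = np.random.default_rng(ss)
        out = _run_chain(
            y, X, W, Z, hen_idx, n_i, H, p, q, k, dim, pos4, shift_pairs,
            spec, rng, n_keep, ll_thin
        )
        for name in chains:
            chains[name].append(out[name])
        if out["loglik"] is not None:
            ll_chains.append(out["loglik"])
        acc_d_all.append(out["acc_d"])
        acc_g_all.append(out["acc_g"])

    draws = {name: np.stack(v) for name, v in chains.items()}
    loglik = np.stack(ll_chains) if ll_chains else None

    rhat_max = float("nan")
    converged = True
    if spec.n_chains >= 2:
        pop = {
            "beta": draws["beta"],
            "gamma": draws["gamma"],
            "Sigma_diag": draws["Sigma"][..., pos4, pos4],
        }
        rh = az.rhat(az.convert_to_dataset(pop))
        rhat_max = float(
            max(np.nanmax(np.atleast_1d(rh[v].values)) for v in rh.data_vars)
        )
        converged = bool(rhat_max <= spec.rhat_threshold)
        if not converged:
            warnings.warn(
                f"chains not converged (max R-hat {rhat_max:.3f} > "
                f"{spec.rhat_threshold}); fit flagged"
            )
    return DHGLMFit(
        spec=spec,
        hen_ids=hen_ids,
        mean_fixed_names=mean_names,
        disp_fixed_names=disp_names,
        draws=draws,
        loglik=loglik,
        y=y,
        converged=converged,
        rhat_max=rhat_max,
        accept_d=float(np.mean(acc_d_all)),
        accept_gamma=float(np.mean(acc_g_all)),
    )


def _hen_constant(col, hen_idx, H):
    """Hen values of a column that is constant within hen, or None."""
    firsts = np.zeros(H)
    firsts[hen_idx[::-1]] = col[::-1]
    if np.allclose(col, firsts[hen_idx]):
        return firsts
    return None


def _location_shift_pairs(X, Z, hen_idx, H, spec):
    """Directions in which the likelihood is invariant: shifting a fixed
    effect while compensating through a hen-effect column.  Each pair is
    (hen-effect column, fixed-effect column, per-hen weight vector):
    exact matches between X and Z columns (weight 1) plus fixed covariates
    that are constant within hen (compensated by the hen intercept with the
    hen's covariate value as weight)."""
    term_to_fixed = {"intercept": 0}
    for nm, term in (("time", "slope"), ("time2", "slope2")):
        if nm in spec.mean_fixed:
            term_to_fixed[term] = 1 + spec.mean_fixed.index(nm)
    pairs = [
        (ci, term_to_fixed[term], np.ones(H))
        for ci, term in enumerate(spec.mean_random)
        if term in term_to_fixed
    ]
    matched = {j for _, j, _ in pairs}
    for j in range(1, X.shape[1]):
        if j in matched:
            continue
        w = _hen_constant(X[:, j], hen_idx, H)
        if w is not None and np.any(w != 0):
            pairs.append((0, j, w))
    return pairs


def _run_chain(y, X, W, Z, hen_idx, n_i, H, p, q, k, dim, pos4, shift_pairs,
               spec, rng, n_keep, ll_thin):
    has_d = spec.include_dispersion_random
    # overdispersed initialisation around simple moment estimates
    beta = np.linalg.lstsq(X, y, rcond=None)[0] + rng.normal(0, 0.5, p)
    resid0 = y - X @ beta
    hen_means = np.bincount(hen_idx, resid0, minlength=H) / n_i
    u = np.zeros((H, k))
    u[:, 0] = hen_means + rng.normal(0, 0.2, H)
    d = rng.normal(0, 0.2, H) if has_d else np.zeros(H)
    gamma = np.zeros(q)
    gamma[0] = np.log(max(resid0.std(), 1e-3)) + rng.normal(0, 0.3)
    Sigma = np.eye(dim) * 0.5

    S0 = np.eye(dim) * spec.prior_sigma_scale
    nu0 = max(spec.prior_sigma_df, dim + 2)
    beta_prec = 1.0 / spec.prior_beta_sd**2
    gamma_prec = 1.0 / spec.prior_gamma_sd**2

    step_d = np.full(H, 0.3)
    step_g = 0.1
    acc_d_win = np.zeros(H)
    acc_g_win = 0
    n_win = 0
    acc_d_post = np.zeros(H)
    acc_g_post = 0
    n_post = 0

    kept = {
        "beta": np.empty((n_keep, p)),
        "gamma": np.empty((n_keep, q)),
        "u": np.empty((n_keep, H, k)),
        "d": np.empty((n_keep, H)),
        "Sigma": np.empty((n_keep, 4, 4)),
    }
    ll_list = []
    k_out = 0

    for it in range(spec.n_iter):
        log_sd = W @ gamma + d[hen_idx]
        inv_var = np.exp(-2.0 * log_sd)

        # fixed effects of the mean part (conjugate normal)
        r_u = y - np.einsum("nk,nk->n", Z, u[hen_idx])
        Xw = X * inv_var[:, None]
        A = X.T @ Xw + beta_prec * np.eye(p)
        b = Xw.T @ r_u
        beta = _batched_mvn_sample(A[None], b[None], rng)[0]

        # hen-level mean effects (conjugate, batched over hens)
        if has_d:
            Suu = Sigma[:k, :k]
            sud = Sigma[:k, k]
            sdd = Sigma[k, k]
            cond_cov = Suu - np.outer(sud, sud) / sdd
            cond_mean = np.outer(d, sud / sdd)  # (H,k)
        else:
            cond_cov = Sigma[:k, :k]
            cond_mean = np.zeros((H, k))
        Sinv = np.linalg.inv(cond_cov)
        r_b = y - X @ beta
        Zw = Z * inv_var[:, None]
        P = np.zeros((H, k, k))
        np.add.at(P, hen_idx, Zw[:, :, None] * Z[:, None, :])
        P += Sinv
        rhs = np.zeros((H, k))
        np.add.at(rhs, hen_idx, Zw * r_b[:, None])
        rhs += cond_mean @ Sinv
        u = _batched_mvn_sample(P, rhs, rng)

        resid = r_b - np.einsum("nk,nk->n", Z, u[hen_idx])

        # exact Gibbs draws along the likelihood-invariant shift directions
        Cinv = np.linalg.inv(cond_cov)
        for c, j, w in shift_pairs:
            prec = (w @ w) * Cinv[c, c] + beta_prec
            mean = (((u - cond_mean) @ Cinv[:, c]) @ w
                    - beta_prec * beta[j]) / prec
            delta = mean + rng.standard_normal() / np.sqrt(prec)
            beta[j] += delta
            u[:, c] -= delta * w

        # dispersion hen effects: 1-D Metropolis per hen (vectorised)
        if has_d:
            Sdinv_u = np.linalg.solve(Sigma[:k, :k], Sigma[:k, k])
            m_d = u @ Sdinv_u
            s2_d = max(Sigma[k, k] - Sigma[:k, k] @ Sdinv_u, 1e-10)
            Q = np.bincount(
                hen_idx, resid**2 * np.exp(-2.0 * (W @ gamma)), minlength=H
            )

            def logp_d(dd):
                return (
                    -n_i * dd
                    - 0.5 * Q * np.exp(-2.0 * dd)
                    - 0.5 * (dd - m_d) ** 2 / s2_d
                )

            prop = d + step_d * rng.standard_normal(H)
            logr = logp_d(prop) - logp_d(d)
            accept = np.log(rng.random(H)) < logr
            d = np.where(accept, prop, d)
            if it < spec.n_burn:
                acc_d_win += accept
            else:
                acc_d_post += accept

        # dispersion fixed effects: block Metropolis
        def logp_g(g):
            ls = W @ g + d[hen_idx]
            return float(
                -np.sum(ls) - 0.5 * np.sum(resid**2 * np.exp(-2.0 * ls))
                - 0.5 * gamma_prec * g @ g
            )

        gprop = gamma + step_g * rng.standard_normal(q)
        if np.log(rng.random()) < logp_g(gprop) - logp_g(gamma):
            gamma = gprop
            if it < spec.n_burn:
                acc_g_win += 1
            else:
                acc_g_post += 1

        # exact location shift between gamma[0] and the d field
        if has_d:
            m_sh = u @ Sdinv_u
            prec = H / s2_d + gamma_prec
            mean = ((d - m_sh).sum() / s2_d - gamma_prec * gamma[0]) / prec
            delta = mean + rng.standard_normal() / np.sqrt(prec)
            gamma[0] += delta
            d = d - delta

        # hen-level covariance (conjugate inverse-Wishart)
        V = np.column_stack([u, d]) if has_d else u
        Sigma = stats.invwishart.rvs(
            df=nu0 + H, scale=S0 + V.T @ V, random_state=rng
        )
        Sigma = np.atleast_2d(Sigma)

        if it < spec.n_burn:
            n_win += 1
            if n_win == 50:
                if has_d:
                    step_d *= np.exp(acc_d_win / 50 - 0.44)
                    acc_d_win[:] = 0
                step_g *= np.exp(acc_g_win / 50 - 0.30)
                acc_g_win = 0
                n_win = 0
        else:
            n_post += 1
            j = it - spec.n_burn
            if j % spec.thin == 0 and k_out < n_keep:
                kept["beta"][k_out] = beta
                kept["gamma"][k_out] = gamma
                kept["u"][k_out] = u
                kept["d"][k_out] = d
                S4 = np.zeros((4, 4))
                S4[np.ix_(pos4, pos4)] = Sigma
                kept["Sigma"][k_out] = S4
                if ll_thin is not None and (k_out % ll_thin == 0):
                    ls = W @ gamma + d[hen_idx]
                    mu = X @ beta + np.einsum("nk,nk->n", Z, u[hen_idx])
                    ll_list.append(
                        -0.5 * np.log(2 * np.pi) - ls
                        - 0.5 * (y - mu) ** 2 * np.exp(-2.0 * ls)
                    )
                k_out += 1

    out = {k: v[:k_out] for k, v in kept.items()}
    out["loglik"] = np.stack(ll_list) if ll_list else None
    out["acc_d"] = (
        float(np.mean(acc_d_post) / max(n_post, 1)) if has_d else float("nan")
    )
    out["acc_g"] = acc_g_post / max(n_post, 1)
    return out


def predictability_estimates(fit: DHGLMFit) -> pd.DataFrame:
    """Per-hen predictability: the sign-flipped posterior mean of the
    dispersion intercept d_i (higher = lower residual SD = more
    predictable), with its posterior SD."""
    d = fit.draws["d"].reshape(-1, len(fit.hen_ids))
    return pd.DataFrame(
        {
            "hen_id": fit.hen_ids,
            "predictability": -d.mean(axis=0),
            "predictability_sd": d.std(axis=0, ddof=1),
        }
    ).set_index("hen_id")


def coefficient_of_variation_predictability(fit: DHGLMFit) -> IntervalEstimate:
    """CVp = sqrt(exp(V_d) - 1) per posterior draw of the among-hen
    dispersion variance V_d; posterior mean and 95% percentile interval."""
    vd = fit.v_d_draws().ravel()
    cvp = np.sqrt(np.expm1(np.clip(vd, 0, None)))
    lo, hi = np.percentile(cvp, [2.5, 97.5])
    point = float(cvp.mean())
    return IntervalEstimate(
        point=point,
        lower95=float(min(lo, point)),
        upper95=float(max(hi, point)),
        n_draws=cvp.size,
    )


def _loo_pointwise(fit: DHGLMFit):
    if fit.loglik is None:
        raise ValueError("fit carries no pointwise log-likelihood draws")
    idata = az.from_dict(log_likelihood={"y": fit.loglik})
    # no posterior group is attached, so the relative efficiency defaults to 1
    return az.loo(idata, pointwise=True, reff=1.0)


def loo_compare(fit_full: DHGLMFit, fit_null: DHGLMFit):
    """PSIS-LOO comparison: positive elpd difference favours the full
    (dispersion) model.  Returns (elpd_diff, se_diff, n_high_pareto_k)."""
    loo_f = _loo_pointwise(fit_full)
    loo_n = _loo_pointwise(fit_null)
    pf = np.asarray(loo_f.loo_i)
    pn = np.asarray(loo_n.loo_i)
    if pf.shape != pn.shape:
        raise ValueError("models were not fitted to identical data")
    diff = pf - pn
    se = float(np.sqrt(len(diff) * np.var(diff, ddof=1)))
    n_high = int(np.sum(np.asarray(loo_f.pareto_k) > 0.7)) + int(
        np.sum(np.asarray(loo_n.pareto_k) > 0.7)
    )
    return float(diff.sum()), se, n_high


def convergence_report(fit: DHGLMFit) -> pd.DataFrame:
    """Split-R-hat and bulk ESS for every sampled parameter, plus a
    posterior-predictive overlay of the response mean and SD (in
    ``.attrs``)."""
    if fit.draws["beta"].shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    rows = []

    def add(name, arr):  # arr: (chains, draws)
        rows.append(
            {
                "parameter": name,
                "rhat": float(az.rhat(arr[None] if arr.ndim == 1 else arr)),
                "ess_bulk": float(az.ess(arr)),
            }
        )

    for k, names in (("beta", fit.mean_fixed_names), ("gamma", fit.disp_fixed_names)):
        for j, nm in enumerate(names):
            add(f"{k}[{nm}]", fit.draws[k][:, :, j])
    for i, hen in enumerate(fit.hen_ids):
        for j, term in enumerate(fit.spec.mean_random):
            add(f"u[{hen},{term}]", fit.draws["u"][:, :, i, j])
        if fit.spec.include_dispersion_random:
            add(f"d[{hen}]", fit.draws["d"][:, :, i])
    pos = fit.re_positions
    for a in pos:
        for b in pos:
            if b < a:
                continue
            add(f"Sigma[{RE_TERMS[a]},{RE_TERMS[b]}]", fit.draws["Sigma"][:, :, a, b])
    report = pd.DataFrame(rows)

    # posterior predictive mean/SD overlay
    C, S, _ = fit.draws["beta"].shape
    report.attrs["observed_mean"] = float(fit.y.mean())
    report.attrs["observed_sd"] = float(fit.y.std(ddof=1))
    return report
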