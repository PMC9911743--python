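# Methods

Statistical details of each stage. Notation: hens are indexed by *i*, days
post-transfer by *t* (starting at 1, uncentred).

## Daily movement variables

The raw input is a zone-entry log: one row per (hen, timestamp, zone entered)
over five zones — litter and winter garden at level 0, lower tier (1),
nestbox tier (2), top tier (3). Validation requires known zones,
per-hen non-decreasing timestamps, and collapses consecutive duplicate
zones (keeping the first timestamp).

For each hen-day, over the lit period (lights-on to lights-off):

- **percent time per zone** — occupancy seconds / lit seconds × 100; a day
  is *complete* only if a record at or before lights-on pins down the
  starting zone;
- **stays per hour per zone** — number of distinct visits (runs) per lit
  hour; the run in progress at lights-on counts;
- **travelled vertical distance per hour** — for each transition, the
  number of tier boundaries crossed, |level(b) − level(a)|, so top tier →
  litter counts 3 and litter → winter garden 0; summed and divided by lit
  hours;
- **winter-garden prompt entry** — 1 if the hen enters the winter garden
  within 15 minutes of its opening (0 whenever it is closed);
- **sleeping height** — the level of the zone occupied for the longest
  total time between lights-off and the next lights-on.

A **no-transition day** is a tracked day with no zone change strictly inside
the lit period; the per-hen count over the study is a welfare covariate.
Uncovered hen-days yield NaN rather than a silent zero.

The extractor is tested against a brute-force oracle that re-computes every
variable from a one-second discretisation of the log.

## Composite daily movement score

Because hens contribute unequal numbers of complete days, the PCA is fitted
on a balanced weekly subset: the earliest complete, winter-garden-available
day of each hen × 7-day block (blocks counted from the hen's first eligible
day). The correlation-matrix PCA of the 13 variables yields loadings and
eigenvalues; components with eigenvalue > 1 are reported as retained. PC1 is
sign-anchored so travelled vertical distance loads positively (higher score
= more movement). All hen-days are standardized with the *subset* means and
SDs and projected onto PC1, giving the daily score y_it used downstream. By
construction, projecting the fitting subset itself gives scores with mean 0
and variance equal to the first eigenvalue (at ddof = 1), which the tests
assert exactly.

## Reaction norms (REML mixed-model ladder)

Three nested Gaussian mixed models with hen as the grouping factor:

    RI:   y_it = x_it'β + b0_i + e_it
    RS1:  + b1_i·t                (2×2 hen covariance)
    RS2:  + b2_i·t²               (3×3 hen covariance)

with fixed effects time, time², hatching treatment and standardized daily
temperature. Fitting is REML (statsmodels MixedLM); the default optimizer is
tried first, then powell and cg; candidates with a non-finite restricted
likelihood — a degenerate optimum some optimizers report as converged — are
discarded, and converged fits with the highest likelihood win. Rungs are
compared with likelihood-ratio tests on the restricted likelihood (identical
fixed effects enforced; df 2 and 3 up the ladder). No boundary-mixture
correction is applied, which makes the tests conservative; a 200-replicate
null experiment in the acceptance suite checks the empirical type-I rate
stays at or below 5%.

**Adjusted repeatability** from the RI rung is R = V_id/(V_id + V_res),
"adjusted" because fixed effects are held in the model. Its 95% interval
simulates (log V_id, log V_res) from the asymptotic normal approximation at
the REML optimum, with curvature taken from a numerically differentiated
closed-form RI restricted likelihood (compound-symmetry Woodbury identity,
independent of the fitting path). Coverage is checked empirically in the
acceptance suite (200 replicates with known R = 0.5).

**Population peak day**: the quadratic population trend peaks at
−β₁/(2β₂); reported as NaN when β₂ ≥ 0.

Per-hen effects are summarised by draws from the conditional (BLUP)
distribution; marginal and conditional R² use the mean-covariate formulation
for the random-slope contribution.

## Predictability (DHGLM)

    y_it ~ Normal(μ_it, σ_it²)
    μ_it = x_it'β + b0_i + b1_i·t + b2_i·t²
    log σ_it = w_it'γ + d_i
    (b0, b1, b2, d)_i ~ MVN(0, Σ)

d_i is the hen's dispersion intercept; its sign-flipped posterior mean is
the hen's **predictability**. The population spread is summarised as
CVp = √(exp(V_d) − 1), the coefficient of variation of hen residual SDs
implied by the lognormal with among-hen variance V_d = Σ[d,d].

Sampling is Metropolis-within-Gibbs: conjugate normal updates for β and the
mean-part hen effects (batched per hen), adaptive random-walk Metropolis for
γ and each d_i, and a conjugate inverse-Wishart update for Σ. Two remedies
keep mixing healthy: (1) exact Gibbs draws along likelihood-invariant
directions — shifting a fixed effect while compensating through the matching
hen-effect column (intercept/time/time² exactly; hen-constant covariates
through the hen intercept, weighted by the covariate), and the analogous
shift between γ₀ and the d field; (2) the random structure of the mean part
(`mean_random`) can be reduced to the intercept when the data carry no slope
variance, avoiding boundary-stuck covariance components. Convergence is
summarised by split-R-hat on the population-level parameters (threshold
1.05) and never raises — downstream code checks the flag. Model comparison
(dispersion effect vs none) uses PSIS-LOO on pointwise log-likelihood draws.

## Welfare association (bivariate Bayesian model)

Movement scores y_it (repeated) and one welfare score k_i per hen
(keel-bone-fracture severity or feather damage, 0–100):

    y_it = x_it'β_m + a0_i + a1_i·t + a2_i·t² + e_it
    k_i  = x_i'β_w + p_pen(i) + aw_i + ε_i
    (a0, a1, a2, aw)_i ~ MVN(0, G2),  p_pen ~ Normal(0, g1)

Welfare fixed effects: predictability, no-transition-day count, treatment,
early-life class and standardized body mass. Because k_i has no replicates,
its residual variance is pinned at 1e-4 with zero residual cross-covariance;
the hen deviation aw_i plays the residual's role and G2 carries the
welfare–movement associations (reported as posterior correlations with 95%
intervals). The near-zero residual makes welfare locations nearly collinear,
so the welfare-side block (β_w, pen effects, aw) is drawn by composition
with aw integrated out of the first two conditionals, and the same
likelihood-invariant location shifts as in the DHGLM are applied to the
movement side — without them, hen-constant covariates keep lag-1
autocorrelations near 0.96; with them the chains mix essentially
independently. Priors: effectively flat normals on fixed effects,
inverse-Wishart(4 + H, I) for G2, scaled-inverse-χ² for the movement
residual and pen variance.

## Synthetic data generator

One 4-vector of correlated hen effects (intercept, slope, slope²,
dispersion) drives everything. Daily scores follow the DHGLM generating
equation directly. Transition logs come from a continuous-time Markov chain
over the zones (exponential dwell times, adjacency-restricted jumps, winter
garden reachable only while open, one sleeping zone per night) whose per
hen-day activity multiplier is exp(0.3·η_it/SD(b0) + ε), with η_it the hen's
reaction-norm mean and ε day noise with SD 0.3·exp(d_i) — so the generating
heterogeneity in level, trend and predictability is all expressed in the
logs. Welfare scores are linear in predictability and the no-transition-day
count plus pen and residual noise, clipped to 0–100 (the clipped fraction is
reported). An `empirical` option rescales the drawn hen effects so their
sample covariance equals the target exactly (the classic
`mvrnorm(empirical = TRUE)` device); the calibrated recovery benchmarks use
it to remove finite-population noise from their targets.

## Calibrated recovery benchmarks

Each benchmark (`hennorm.benchmarks`) simulates populations whose generating
values equal the quantity under test, at 80 hens × 47 days, and averages a
few replicates: repeatability 0.44 (intercept variance 11, residual 14), the
intercept–slope correlation −0.79, the activity peak at day 39 (β₁ = 0.078,
β₂ = −0.001, hen intercept SD 1, residual SD 1; the vertex is computed from
replicate-averaged coefficients because the per-replicate ratio is
heavy-tailed), CVp 0.25 (V_d = 0.0606), and welfare coefficients 23.54 on
predictability (SD 0.25) and 5.12 on no-transition days (noise SD 10).
`scripts/acceptance.py` recomputes all of them from one root seed.
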