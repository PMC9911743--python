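"""Predictability: the double-hierarchical Gaussian model (DHGLM).

Hens differ not only in their average movement but in how variable they are
from day to day.  The DHGLM places a hen-level random intercept in the
log-residual-SD part of the model; its sign-flipped posterior mean is the
hen's predictability, and the population spread is summarised by CVp.
"""

import hennorm

cfg = hennorm.SimConfig(n_hens=40, n_days=40, seed=3)
truth = hennorm.make_population(cfg)
scores = hennorm.simulate_daily_scores(truth, cfg)

spec = hennorm.DHGLMSpec(n_chains=2, n_iter=6000, seed=3)
fit = hennorm.fit_dhglm(scores, spec)
print(f"converged: {fit.converged} (max R-hat {fit.rhat_max:.3f}); "
      f"d acceptance {fit.accept_d:.2f}")

cvp = hennorm.coefficient_of_variation_predictability(fit)
print(f"CVp = {cvp.point:.2f} [{cvp.lower95:.2f}, {cvp.upper95:.2f}] "
      f"(truth {truth.true_cvp:.2f})")

pred = hennorm.predictability_estimates(fit)
print("\nmost and least predictable hens:")
ranked = pred.sort_values("predictability")
print(ranked.tail(3).round(3).to_string())
print(ranked.head(3).round(3).to_string())

# is the dispersion random effect worth having?  PSIS-LOO comparison
null_spec = hennorm.DHGLMSpec(
    n_chains=2, n_iter=6000, seed=3, include_dispersion_random=False
)
null_fit = hennorm.fit_dhglm(scores, null_spec)
diff, se, n_high = hennorm.loo_compare(fit, null_fit)
print(f"\nLOO elpd difference (full - null): {diff:.1f} +/- {se:.1f} "
      f"({n_high} high Pareto-k points)")
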