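"""Associate individual movement metrics with end-of-lay welfare.

A bivariate Bayesian model links the repeated daily movement score and one
welfare score per hen (keel-bone-fracture severity) through a joint
hen-level covariance, with predictability and the early no-transition-day
count as welfare-side fixed effects.
"""

import numpy as np
import pandas as pd

import hennorm

cfg = hennorm.SimConfig(n_hens=50, n_days=20, seed=19, empirical=True)
truth = hennorm.make_population(cfg)
scores = hennorm.simulate_daily_scores(truth, cfg)

rng = np.random.default_rng(19)
pred = pd.Series(-truth.d, index=truth.hen_ids, name="predictability")
ntd = pd.Series(rng.binomial(3, 0.13, cfg.n_hens), index=truth.hen_ids,
                name="no_transition_days")
welfare_scores = hennorm.simulate_welfare(truth, cfg, pred, ntd)
pred_table = pd.DataFrame(
    {"predictability": pred, "predictability_sd": 0.0}
).rename_axis("hen_id")

fit = hennorm.fit_bivariate(
    scores, welfare_scores, pred_table, ntd,
    n_iter=8000, n_burn=2000, thin=6, n_chains=2, seed=19,
)
print(f"converged: {fit.converged} (max R-hat {fit.rhat_max:.3f})")

summary = hennorm.fixed_effect_summary(fit)
kbf = summary[summary["response"] == "kbf"]
print("\nwelfare (keel-bone fracture) fixed effects:")
print(kbf.drop(columns="response").round(2).to_string(index=False))

corr = hennorm.random_effect_correlations(fit)
print("\nhen-level correlations with the welfare deviation:")
print(corr[corr["term_b"] == "welfare"].round(2).to_string(index=False))
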