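"""Build the composite daily movement score (PC1).

The PCA is fitted on a balanced weekly subset (one complete day per hen and
7-day block) so every hen and week carries equal weight; all hen-days are
then projected onto the first component, whose sign is anchored so that
travelled vertical distance loads positively.
"""

import hennorm

cfg = hennorm.SimConfig(n_hens=12, n_days=28, seed=7)
truth = hennorm.make_population(cfg)
log = hennorm.simulate_transition_log(truth, cfg)
daily = hennorm.daily_variables(log, cfg.calendar)

subset = hennorm.weekly_subset(daily)
print(f"weekly subset: {len(subset)} hen-days from {len(daily)}")

model = hennorm.fit_pca(subset)
frac = model.explained_fraction()
print(f"PC1 explains {100 * frac[0]:.0f}% of the variance; "
      f"{model.n_retained} components with eigenvalue > 1")
print("\ntop PC1 loadings:")
loads = sorted(zip(model.variables, model.loadings[:, 0]),
               key=lambda t: -abs(t[1]))
for name, w in loads[:5]:
    print(f"  {name:28s} {w:+.2f}")

scores = hennorm.project_pc1(
    model, daily, covariates=truth.covariates, temperature=truth.temperature
)
print(f"\nscore table: {len(scores)} rows")
print(scores[["hen_id", "day", "pc1", "time", "treatment"]]
      .head(5).round(3).to_string(index=False))
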