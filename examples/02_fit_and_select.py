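"""Fit the probit BART classifier and select features against permutation nulls.

A feature's importance is its inclusion proportion -- the fraction of all
splitting rules in the posterior that use it.  Selection refits the model on
label-permuted data and keeps a feature only when its true inclusion
proportion exceeds the 0.95 quantile of its own permutation null.
"""

import bartomics as bo

spec = bo.CohortSpec(n_controls=60, n_cases=60,
                     main_effects=(("M3", 2.0), ("OTU5", 1.5)), seed=7)
table = bo.simulate_cohort(spec)

config = bo.BartConfig(m=50, n_burn=250, n_post=500, seed=7)
posterior = bo.fit_probit(table, config)

pred = bo.predict(posterior, table)
acc = ((pred.prob_mean > 0.5).astype(int) == table.outcome).mean()
print(f"in-sample accuracy: {acc:.2f}")

profile = bo.inclusion_proportions(posterior)
print("\ntop 5 inclusion proportions:")
print(profile.as_series().sort_values(ascending=False).head().round(3))

sel_config = bo.SelectionConfig(n_permutations=50, quantile=0.95, seed=7)
result = bo.select_features(table, config, sel_config)
print("\nselected features:", result.selected_features)
print(result.to_frame().sort_values("inclusion_proportion",
                                    ascending=False).head(8).round(3))
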