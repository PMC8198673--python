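"""Simulate a linked microbiome-metabolome case/control cohort.

The generator mirrors the shape of stool-sample studies: zero-inflated
compositional 16S counts, log-normal metabolite intensities, age/sex
covariates, and a probit outcome model with planted effects on standardised
transformed features.  Class counts are exact, not just expected.
"""

import numpy as np

import bartomics as bo

spec = bo.CohortSpec(
    n_controls=102, n_cases=36,          # imbalanced, like a real cohort
    n_taxa=30, n_metabolites=40,
    main_effects=(("M3", 1.5), ("OTU5", 1.0)),
    interaction_effects=(("M1", "M2", 1.2),),
    seed=42,
)
table = bo.simulate_cohort(spec)

print(f"{table.n_samples} samples x {table.n_features} features")
print("cases:", int(table.outcome.sum()), "controls:",
      int((1 - table.outcome).sum()))

mic = table.layers == bo.MICROBIOME
zero_frac = (table.values[:, mic] == 0).mean()
print(f"zero fraction in the OTU block: {zero_frac:.2f}")

# planted effects shift the standardised feature between classes
Z = bo.transformed_standardized(table)
for fid in ("M3", "OTU5"):
    col = Z[:, table.column(fid)]
    d = col[table.outcome == 1].mean() - col[table.outcome == 0].mean()
    print(f"{fid}: case-control shift on the z-scale = {d:+.2f}")

bo.write_table(table, "cohort.tsv")
print("wrote cohort.tsv (TSV with name|layer headers; reload with read_table)")
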