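"""Heavily imbalanced RNA-seq: iterated undersampled DE, RFE, and list overlap.

With 459 tumour vs 41 normal samples the majority class is split into 11
disjoint blocks of 41; each block is tested against the normals, p-values are
BH-adjusted, and gene lists form at a ladder of cutoffs.  Genes significant
in *every* iteration are the consensus; recursive feature elimination then
refines a compact marker set per iteration.
"""

import bartomics as bo

counts, labels = bo.simulate_counts(
    300, n_normal=41, n_tumour=459,
    fold_changes={"G0001": 4.0, "G0002": 0.25, "G0003": 3.0, "G0004": 1.6},
    seed=5)

config = bo.DEConfig(group_size=41, seed=5)
report = bo.undersample_union_de(counts, labels, config)

print(f"{report.n_iterations} disjoint undersampling iterations")
for cutoff in config.cutoff_ladder:
    u = report.per_cutoff_union[cutoff]
    c = report.per_cutoff_consensus[cutoff]
    print(f"  cutoff {cutoff}: union {len(u)} genes, consensus {len(c)}")
print("consensus at the final cutoff:", report.consensus)
print("directions:", {g: report.directions[g] for g in report.consensus})

# RFE on the consensus genes plus some noise genes, BART ranker
noise = [g for g in counts.index if g not in report.consensus][:12]
sub = counts.loc[report.consensus + noise]
rfe = bo.rfe_union(sub, labels, step=2, config=config, n_select=3)
print(f"\nRFE over {rfe.n_iterations} iterations -> union {rfe.union}")
print("recurrent (picked in >1 iteration):", rfe.recurrent)

# compare against an external list with directions
external = [("G0001", "up"), ("G0002", "up"), ("G0100", "down")]
ours = [(g, report.directions[g]) for g in report.consensus]
print("\noverlap with the external list:")
print(bo.overlap_gene_lists(ours, external))
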