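# bartomics

Bayesian sum-of-trees (BART) workflows for multiomics case/control studies:
simulate linked microbiome–metabolome cohorts, fit a probit BART classifier by
backfitting MCMC, select markers against permutation nulls, mine pairwise
interactions from tree paths, draw partial-dependence risk surfaces, and run
class-imbalance-aware transcriptomics gene-list procedures.

## Why BART for multiomics?

Microbiome and metabolome case/control studies face small cohorts, thousands
of candidate features, non-linear effects, and interactions across omics
layers. BART addresses this with an ensemble of small regression trees under
regularising priors:

* **Model.** `P(Y = 1 | x) = Φ(f(x) + c)` with `f(x) = Σₖ Tₖ(x)` a sum of `m`
  trees and `c = Φ⁻¹(case fraction)` a fixed offset. Fitting uses the standard
  latent-variable scheme for binary outcomes: truncated-normal latents, then a
  backfitting sweep with grow/prune/change Metropolis–Hastings moves and
  conjugate leaf draws per tree.
* **Importance.** A feature's *inclusion proportion* — the fraction of all
  splitting rules in the posterior that use it — measures importance. Keeping
  the forest small makes features compete for splits, which is what makes
  this informative.
* **Selection.** Refit on label-permuted data; keep a feature only when its
  true inclusion proportion exceeds the 0.95 quantile of its own permutation
  null ("local thresholding").
* **Interactions.** Count, over all posterior trees, how often two features
  split on the same root-to-terminal path; top-ranked pairs are interaction
  candidates.
* **Interpretation.** Partial dependence with posterior credible bands, and
  two-feature risk surfaces on the log-odds scale (0 = equal risk).

The MCMC engine is implemented from scratch on flat numba-compiled arrays;
standard statistical steps (stratified cross-validation, BH correction, Welch
tests) use scikit-learn, statsmodels and scipy.

## Worked example

```python
import bartomics as bo

# an imbalanced cohort with two planted metabolite effects
spec = bo.CohortSpec(n_controls=102, n_cases=36,
                     main_effects=(("M1", 1.5), ("M2", 1.5)), seed=11)
table = bo.simulate_cohort(spec)

# consensus selection over balanced resamples, then CV error per layer set
reports = bo.compare_layers(
    table,
    bo.PipelineConfig(n_repeats=10, cv_folds=5, seed=11),
    bo.BartConfig(m=20, n_burn=150, n_post=300),
    bo.SelectionConfig(n_permutations=20, quantile=0.95, seed=11))
for layers, rep in reports.items():
    print(layers, rep.consensus, rep.oos_error)
```

Output:

```
('microbiome',) [] None
('microbiome', 'metabolome') ['M1', 'M2'] 0.123
```

The microbiome-only model finds no consensus markers on this cohort (the
signal is metabolite-borne), while the combined model recovers exactly the two
planted metabolites and classifies held-out samples at 12.3% error — the
multi-omics gain the pipeline is designed to expose. The scripts in
`examples/` walk through each stage (simulation, fitting and selection,
interaction mining and risk surfaces, layer comparison, transcriptome
undersampling) with printed results.

## Command line

Each stage is also a subcommand writing plain TSV/JSON artifacts plus a run
manifest:

```bash
bartomics simulate --effect M1=1.5 --seed 11 --out cohort.tsv
bartomics fit      --table cohort.tsv --out posterior.json
bartomics select   --table cohort.tsv --out selection.tsv
bartomics interactions --fit posterior.json --out pairs.tsv
bartomics pd       --fit posterior.json --table cohort.tsv --feature M1 --out pd.tsv
bartomics pipeline --table cohort.tsv --out report.json
bartomics de       --counts counts.tsv --out genes.json
bartomics rfe      --counts counts.tsv --out rfe.json
bartomics overlap  --list-a a.tsv --list-b b.tsv --out overlap.tsv
```

## Transcriptomics under heavy imbalance

For bulk RNA-seq with, say, 459 tumour vs 41 normal samples,
`undersample_union_de` partitions the majority class into ⌊459/41⌋ = 11
disjoint blocks, tests each against the minority class (Welch t on log-CPM by
default; the test is pluggable), BH-adjusts, and reports per-cutoff unions and
the across-iteration consensus with up/down directions. `rfe_union` runs
recursive feature elimination (BART inclusion proportions as the default
ranker) per iteration, and `overlap_gene_lists` compares lists with direction
concordance.

## Reproduction

The verification battery behind the test suite can be run standalone:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes the computed quantities (prior split-rate recovery at depths 0–2,
conjugate-oracle z-score, null selection rate, planted-effect recovery counts,
interaction top-2% hits, partial-dependence identity residuals, layer-ordering
wins, undersampling iteration count, BH oracle error, overlap counts) as JSON,
one `{"value": ..., "n": ...}` entry each. `docs/methods.md` documents the
model, priors, numerical choices, and the scope and limitations of the
synthetic generators.
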