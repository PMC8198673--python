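"""Cohort workflow: balanced resampling, consensus selection, cross-validated
out-of-sample error, and single- vs multi-omics comparison.

When controls heavily outnumber cases, selection is run on repeated balanced
resamplings (all cases plus an equal-size random subset of controls) and
features are aggregated by how often they are selected across repeats; the
consensus set keeps features selected in at least half of the runs.  A final
cross-validated probit BART model restricted to the consensus features (plus
covariates) yields the out-of-sample misclassification error, and the same
machinery run per omics-layer configuration compares, e.g., microbiome-only
against combined microbiome + metabolome models.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._seeds import stage_seed
from .bart import BartConfig, fit_probit, predict
from .cohort import COVARIATE, FeatureTable
from .selection import SelectionConfig, select_features


@dataclass
class PipelineConfig:
    n_repeats: int = 10
    min_freq: Optional[int] = None  # default: at least half of the repeats
    cv_folds: int = 5
    layers_to_use: Tuple[str, ...] = ("microbiome", "metabolome")
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.min_freq is None:
            self.min_freq = math.ceil(self.n_repeats / 2)
        if not 1 <= self.min_freq <= self.n_repeats:
            raise ValueError("min_freq must lie in [1, n_repeats]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class PipelineReport:
    per_repeat_selected: list  # list of feature-id sets
    frequencies: dict  # feature -> number of repeats selected
    consensus: list  # frequency >= min_freq, sorted
    always_selected: list  # frequency == n_repeats, sorted
    oos_error: Optional[float]  # None when the consensus set is empty
    layers: Tuple[str, ...]
    config: PipelineConfig

    def __post_init__(self):
        union = set().union(*self.per_repeat_selected) \
            if self.per_repeat_selected else set()
        if not set(self.always_selected) <= set(self.consensus) <= union:
            raise ValueError("always-selected ⊆ consensus ⊆ union must hold")

    def frequency_frame(self):
        import pandas as pd
        items = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["feature", "frequency"])


def balanced_resample(outcome: np.ndarray, seed: int) -> np.ndarray:
    """All minority-class samples plus an equal-size uniform subset of the
    majority class; the identity (all samples) when classes are balanced."""
    outcome = np.asarray(outcome)
    idx0 = np.where(outcome == 0)[0]
    idx1 = np.where(outcome == 1)[0]
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present")
    if len(idx0) == len(idx1):
        return np.arange(len(outcome))
    minority, majority = (idx1, idx0) if len(idx1) < len(idx0) else (idx0, idx1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, chosen]))


def run_selection_repeats(table: FeatureTable, config: PipelineConfig,
                          bart_config: BartConfig,
                          sel_config: SelectionConfig) -> PipelineReport:
    """Repeat balanced resampling + permutation selection; aggregate by
    selection frequency (out-of-sample error not yet attached)."""
    sub = table.select_layers(config.layers_to_use, keep_covariates=True)
    per_repeat = []
    for rep in range(config.n_repeats):
        idx = balanced_resample(sub.outcome,
                                stage_seed(config.seed, "resample", rep))
        rep_table = sub.take(idx)
        rep_sel = SelectionConfig(
            n_permutations=sel_config.n_permutations,
            quantile=sel_config.quantile,
            seed=stage_seed(config.seed, "repeat-select", rep),
            perm_n_post=sel_config.perm_n_post)
        res = select_features(rep_table, bart_config, rep_sel)
        per_repeat.append(set(res.selected_features))

    freq = Counter()
    for s in per_repeat:
        freq.update(s)
    consensus = sorted(f for f, c in freq.items() if c >= config.min_freq)
    always = sorted(f for f, c in freq.items() if c == config.n_repeats)
    return PipelineReport(per_repeat_selected=per_repeat,
                          frequencies=dict(freq), consensus=consensus,
                          always_selected=always, oos_error=None,
                          layers=tuple(config.layers_to_use), config=config)


def cv_oos_error(table: FeatureTable, features: Sequence[str],
                 bart_config: BartConfig, cv_folds: int = 5,
                 seed: int = 0) -> float:
    """Stratified k-fold out-of-sample misclassification error.

    Fits on each training split restricted to the given features plus all
    covariates, classifies the held-out samples at probability 0.5, and pools
    the misclassification fraction across folds.
    """
    features = list(features)
    if not features:
        raise ValueError("feature set must be non-empty")
    covs = [f for f, l in zip(table.feature_ids, table.layers)
            if l == COVARIATE and f not in features]
    model_table = table.restrict(features + covs)
    y = model_table.outcome
    if cv_folds > min(np.bincount(y)):
        raise ValueError("cv_folds exceeds the minority class size")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = 0
    for fold, (tr, te) in enumerate(skf.split(model_table.values, y)):
        cfg = BartConfig(**{**bart_config.to_dict(),
                            "seed": stage_seed(seed, "cv-fit", fold)})
        post = fit_probit(model_table.take(tr), cfg)
        prob = predict(post, model_table.take(te)).prob_mean
        errors += int(((prob > 0.5).astype(int) != y[te]).sum())
    return errors / len(y)


def run_pipeline(table: FeatureTable, config: PipelineConfig,
                 bart_config: BartConfig,
                 sel_config: SelectionConfig) -> PipelineReport:
    """Full workflow: selection repeats, consensus, then cross-validated error
    of the consensus model on the full (unbalanced) cohort."""
    report = run_selection_repeats(table, config, bart_config, sel_config)
    if report.consensus:
        sub = table.select_layers(config.layers_to_use, keep_covariates=True)
        report.oos_error = cv_oos_error(
            sub, report.consensus, bart_config, config.cv_folds,
            stage_seed(config.seed, "cv"))
    return report


def compare_layers(table: FeatureTable, config: PipelineConfig,
                   bart_config: BartConfig, sel_config: SelectionConfig,
                   layer_configs: Sequence[Tuple[str, ...]] = (
                       ("microbiome",), ("microbiome", "metabolome"))) -> dict:
    """Run the full pipeline once per layer configuration on identical
    resampling seeds; returns {layer tuple: PipelineReport}."""
    out = {}
    for layers in layer_configs:
        missing = set(layers) - set(map(str, table.layers))
        if missing:
            raise ValueError(f"requested layers not in table: {sorted(missing)}")
        cfg = PipelineConfig(n_repeats=config.n_repeats,
                             min_freq=config.min_freq,
                             cv_folds=config.cv_folds,
                             layers_to_use=tuple(layers),
                             seed=config.seed)
        out[tuple(layers)] = run_pipeline(table, cfg, bart_config, sel_config)
    return out
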