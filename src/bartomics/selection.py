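"""Variable importance and selection for the probit sum-of-trees model.

Importance is the *inclusion proportion*: the fraction of all splitting rules
across the posterior draws that use a given feature.  Selection is by local
permutation-null thresholding: the model is refit on response-permuted copies
of the data, each feature's null distribution is its inclusion proportion
across those fits, and a feature is selected when its true inclusion
proportion strictly exceeds a high quantile (default 0.95) of its own null.

Covariates (age, sex) take part in every fit but are excluded from the
selection report: they are adjustment variables, not candidate markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._seeds import stage_seed
from .bart import BartConfig, BartPosterior, fit_probit_arrays
from .cohort import COVARIATE, FeatureTable

logger = logging.getLogger("bartomics")


@dataclass
class InclusionProfile:
    """Per-feature fractions of all splitting rules in a posterior."""

    feature_ids: list
    proportions: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.feature_ids) != len(self.proportions):
            raise ValueError("one proportion per feature required")
        if (self.proportions < 0).any():
            raise ValueError("proportions must be non-negative")
        s = self.proportions.sum()
        if s > 0 and abs(s - 1.0) > 1e-9:
            raise ValueError("non-zero proportions must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.feature_ids)


@dataclass
class SelectionConfig:
    n_permutations: int = 100
    quantile: float = 0.95
    seed: int = 0
    perm_n_post: Optional[int] = None  # None = same chain length as the true fit

    def __post_init__(self):
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("quantile must lie in (0, 1]")
        # quantiles inside (1 - 1/n, 1) cannot be resolved by n permutations;
        # quantile == 1.0 is the explicit strict-max rule and is allowed.
        if self.quantile < 1.0 and self.quantile > 1.0 - 1.0 / self.n_permutations:
            raise ValueError(
                f"{self.n_permutations} permutations cannot resolve the "
                f"{self.quantile} quantile; increase n_permutations or use 1.0")


def inclusion_proportions(posterior: BartPosterior) -> InclusionProfile:
    """Fraction of all internal splitting rules that use each feature.

    Counts every internal node over all trees and retained draws; a posterior
    of stumps-only forests (zero splits anywhere) yields an all-zero profile
    with a warning rather than an error.
    """
    if posterior.split_counts is not None:
        counts = np.asarray(posterior.split_counts, dtype=float)
        total = float(posterior.total_internal)
    else:
        counts = np.zeros(posterior.n_features)
        internal = posterior.node_feature[posterior.node_feature >= 0]
        for j in internal:
            counts[j] += 1
        total = float(internal.size)
    if total == 0:
        logger.warning("posterior contains no splits; all-zero inclusion profile")
        return InclusionProfile(list(posterior.feature_ids), counts)
    return InclusionProfile(list(posterior.feature_ids), counts / total)


def _null_quantile(null: np.ndarray, quantile: float) -> float:
    """'Higher' empirical-quantile convention: the ceil(q*n)-th order statistic."""
    srt = np.sort(null)
    k = int(np.ceil(quantile * len(srt)))
    return float(srt[k - 1])


@dataclass
class SelectionResult:
    feature_ids: list  # candidate (non-covariate) features
    layers: np.ndarray
    proportions: np.ndarray  # true-fit inclusion proportions (candidates)
    null_quantiles: np.ndarray
    selected: np.ndarray  # boolean
    null_proportions: np.ndarray  # (n_permutations, n_candidates)

    @property
    def selected_features(self) -> list:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_ids,
            "layer": self.layers,
            "inclusion_proportion": self.proportions,
            "null_quantile": self.null_quantiles,
            "selected": self.selected.astype(int),
        })


def select_features(table: FeatureTable, bart_config: BartConfig,
                    sel_config: SelectionConfig) -> SelectionResult:
    """Permutation-null local thresholding on inclusion proportions.

    One fit on the true response, then ``n_permutations`` fits on label-
    permuted copies (the feature matrix is bit-identical across null fits).
    A candidate feature is selected iff its true inclusion proportion strictly
    exceeds the requested quantile of its own null distribution.  Permutation
    fits use the same chain settings as the true fit by default so that, under
    the null, true and permuted inclusion proportions are exchangeable and the
    selection rate is pinned by the quantile; ``perm_n_post`` can shorten them
    at the cost of a conservative threshold.
    """
    X = table.values
    y = table.outcome
    ids = table.feature_ids

    true_cfg = BartConfig(**{**bart_config.to_dict(),
                             "seed": stage_seed(sel_config.seed, "select-true")})
    true_post = fit_probit_arrays(X, y, ids, true_cfg, keep_draws=False)
    true_prop = inclusion_proportions(true_post).proportions

    perm_dict = bart_config.to_dict()
    if sel_config.perm_n_post is not None:
        perm_dict["n_post"] = sel_config.perm_n_post
    rng = np.random.default_rng(stage_seed(sel_config.seed, "select-perm"))
    null = np.empty((sel_config.n_permutations, len(ids)))
    for b in range(sel_config.n_permutations):
        y_perm = rng.permutation(y)
        cfg_b = BartConfig(**{**perm_dict,
                              "seed": stage_seed(sel_config.seed, "select-perm-fit", b)})
        post_b = fit_probit_arrays(X, y_perm, ids, cfg_b, keep_draws=False)
        null[b] = inclusion_proportions(post_b).proportions

    candidate = table.layers != COVARIATE
    cand_idx = np.where(candidate)[0]
    thresholds = np.array([_null_quantile(null[:, j], sel_config.quantile)
                           for j in cand_idx])
    props = true_prop[cand_idx]
    selected = props > thresholds
    return SelectionResult(
        feature_ids=[ids[j] for j in cand_idx],
        layers=table.layers[cand_idx],
        proportions=props,
        null_quantiles=thresholds,
        selected=selected,
        null_proportions=null[:, cand_idx],
    )
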