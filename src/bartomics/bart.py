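"""Sum-of-trees Bayesian probit classifier fit by backfitting MCMC.

The model: P(Y = 1 | x) = Phi(f(x) + c), where f(x) = sum_k T_k(x) is a sum of
m regularised regression trees and c = Phi^{-1}(case fraction) is a fixed
offset.  Fitting follows the standard latent-variable scheme for binary BART:
each iteration draws a truncated-normal latent z_i consistent with y_i given
the current fit, then performs one backfitting sweep in which every tree is
updated against its partial residuals by a grow/prune/change Metropolis-
Hastings proposal followed by conjugate draws of its leaf values (residual
variance fixed at 1 under the probit convention).

Priors regularise the ensemble so that no single tree dominates: a node at
depth d splits with probability alpha * (1 + d)^(-beta), and leaf values are
N(0, sigma_mu^2) with sigma_mu = 3 / (k_leaf * sqrt(m)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import _mcmc
from .cohort import FeatureTable
from .trees import (DecisionTree, SumOfTrees, flat_block_to_tree,
                    forest_to_flat, slots_to_tree, tree_to_slots)

logger = logging.getLogger("bartomics")

MOVE_NAMES = {0: "grow", 1: "prune", 2: "change"}


@dataclass
class BartConfig:
    """Sampler hyperparameters.

    The ensemble size default of 50 reflects the common finding that binary
    BART gains little beyond ~50 trees while a small forest forces features to
    compete for splits, which is what makes inclusion proportions informative.
    """

    m: int = 50
    n_burn: int = 250
    n_post: int = 1000
    alpha_split: float = 0.95
    beta_split: float = 2.0
    k_leaf: float = 2.0
    proposal_probs: Tuple[float, float, float] = (0.28, 0.28, 0.44)
    min_node: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_burn < 0 or self.n_post < 1:
            raise ValueError("chain lengths invalid")
        if not 0.0 < self.alpha_split < 1.0:
            raise ValueError("alpha_split must lie in (0, 1)")
        if self.beta_split < 0:
            raise ValueError("beta_split must be >= 0")
        if self.k_leaf <= 0:
            raise ValueError("k_leaf must be positive")
        pp = self.proposal_probs
        if len(pp) != 3 or any(q <= 0 for q in pp) or abs(sum(pp) - 1) > 1e-9:
            raise ValueError("proposal_probs must be 3 positive values summing to 1")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")

    @property
    def sigma_mu(self) -> float:
        return 3.0 / (self.k_leaf * np.sqrt(self.m))

    def to_dict(self) -> dict:
        return {
            "m": self.m, "n_burn": self.n_burn, "n_post": self.n_post,
            "alpha_split": self.alpha_split, "beta_split": self.beta_split,
            "k_leaf": self.k_leaf, "proposal_probs": list(self.proposal_probs),
            "min_node": self.min_node, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BartConfig":
        d = dict(d)
        if "proposal_probs" in d:
            d["proposal_probs"] = tuple(d["proposal_probs"])
        return cls(**d)


@dataclass
class BartPosterior:
    """Ordered post-burn-in draws of the sum of trees, in flat storage.

    ``tree_offsets`` indexes n_draws * m tree blocks inside the node arrays;
    ``offset`` is the fixed probit intercept added to every prediction.
    """

    node_feature: np.ndarray
    node_threshold: np.ndarray
    node_value: np.ndarray
    node_left: np.ndarray
    node_right: np.ndarray
    tree_offsets: np.ndarray
    n_draws: int
    m: int
    feature_ids: list
    training_ranges: np.ndarray  # (p, 2) observed min/max per feature
    offset: float = 0.0
    config: Optional[BartConfig] = None
    split_counts: Optional[np.ndarray] = None
    total_internal: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.tree_offsets) != self.n_draws * self.m + 1:
            raise ValueError("tree_offsets inconsistent with n_draws * m")
        p = len(self.feature_ids)
        used = self.node_feature[self.node_feature >= 0]
        if used.size and used.max() >= p:
            raise ValueError("tree references an unknown feature index")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def draws(self) -> list:
        """Materialise every draw as a SumOfTrees (intended for small posteriors)."""
        out = []
        for d in range(self.n_draws):
            trees = []
            for t in range(self.m):
                base = int(self.tree_offsets[d * self.m + t])
                trees.append(flat_block_to_tree(
                    self.node_feature, self.node_threshold, self.node_value,
                    self.node_left, self.node_right, base))
            out.append(SumOfTrees(trees))
        return out

    def predict_probit(self, X: np.ndarray) -> np.ndarray:
        """(n_draws, n_samples) matrix of probit values f(x) + offset."""
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}")
        return _mcmc._predict_forest(
            self.node_feature, self.node_threshold, self.node_value,
            self.node_left, self.node_right, self.tree_offsets,
            self.n_draws, self.m, X, self.offset)

    @classmethod
    def from_forests(cls, forests: Sequence[SumOfTrees], feature_ids,
                     training_ranges=None, offset: float = 0.0,
                     config: Optional[BartConfig] = None) -> "BartPosterior":
        nf, nth, nv, nl, nr, offs = forest_to_flat(list(forests))
        feature_ids = list(feature_ids)
        p = len(feature_ids)
        if training_ranges is None:
            training_ranges = np.column_stack([np.zeros(p), np.ones(p)])
        counts = np.zeros(p, np.int64)
        internal = nf[nf >= 0]
        for j in internal:
            counts[j] += 1
        return cls(node_feature=nf, node_threshold=nth, node_value=nv,
                   node_left=nl, node_right=nr, tree_offsets=offs,
                   n_draws=len(forests), m=forests[0].m,
                   feature_ids=feature_ids,
                   training_ranges=np.asarray(training_ranges, dtype=float),
                   offset=offset, config=config,
                   split_counts=counts, total_internal=int(internal.size))

    # -- serialisation -------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "feature_ids": list(self.feature_ids),
            "offset": float(self.offset),
            "seed": self.seed,
            "config": self.config.to_dict() if self.config else None,
            "training_ranges": self.training_ranges.tolist(),
            "draws": [d.to_dict() for d in self.draws],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "BartPosterior":
        doc = json.loads(text)
        forests = [SumOfTrees.from_dict(d) for d in doc["draws"]]
        cfg = BartConfig.from_dict(doc["config"]) if doc.get("config") else None
        post = cls.from_forests(
            forests, doc["feature_ids"],
            training_ranges=np.asarray(doc["training_ranges"], dtype=float),
            offset=float(doc["offset"]), config=cfg)
        post.seed = doc.get("seed")
        return post


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_probit_arrays(X: np.ndarray, y: np.ndarray, feature_ids,
                      config: BartConfig, keep_draws: bool = True,
                      prior_only: bool = False) -> BartPosterior:
    """Fit the probit sum-of-trees model on a raw design matrix."""
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int8)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    classes = np.unique(y)
    if not prior_only and len(classes) < 2:
        raise ValueError("outcome must contain both classes")
    n = X.shape[0]
    const = np.ptp(X, axis=0) == 0
    if const.any() and not prior_only:
        names = [feature_ids[j] for j in np.where(const)[0]]
        logger.warning("constant feature columns retained but never split on: %s",
                       names)

    ybar = np.clip(y.mean(), 1.0 / (n + 1), n / (n + 1.0))
    offset = 0.0 if prior_only else float(ndtri(ybar))

    pg, pp, _ = config.proposal_probs
    (nf, nth, nv, nl, nr, offs, split_counts, total_internal) = _mcmc._run_chain(
        X, y, config.m, config.n_burn, config.n_post,
        config.alpha_split, config.beta_split, config.sigma_mu ** 2,
        pg, pp, config.min_node, offset, config.seed,
        prior_only, keep_draws)

    ranges = np.column_stack([X.min(axis=0), X.max(axis=0)])
    return BartPosterior(
        node_feature=nf, node_threshold=nth, node_value=nv, node_left=nl,
        node_right=nr, tree_offsets=offs, n_draws=config.n_post, m=config.m,
        feature_ids=list(feature_ids), training_ranges=ranges, offset=offset,
        config=config, split_counts=split_counts,
        total_internal=int(total_internal), seed=config.seed)


def fit_probit(table: FeatureTable, config: BartConfig,
               keep_draws: bool = True) -> BartPosterior:
    """Fit the probit BART classifier on a FeatureTable's raw values."""
    return fit_probit_arrays(table.values, table.outcome, table.feature_ids,
                             config, keep_draws=keep_draws)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Posterior predictive summary: per-draw probits and class-1 probabilities."""

    probit_draws: np.ndarray  # (n_draws, n_samples)

    @property
    def prob_draws(self) -> np.ndarray:
        return ndtr(self.probit_draws)

    @property
    def prob_mean(self) -> np.ndarray:
        return self.prob_draws.mean(axis=0)

    @property
    def probit_mean(self) -> np.ndarray:
        return self.probit_draws.mean(axis=0)

    def prob_quantiles(self, qs) -> np.ndarray:
        return np.quantile(self.prob_draws, qs, axis=0)


def _align(posterior: BartPosterior, X) -> np.ndarray:
    if isinstance(X, FeatureTable):
        cols = []
        for f in posterior.feature_ids:
            try:
                cols.append(X.column(f))
            except KeyError:
                raise KeyError(f"prediction input lacks feature {f!r}") from None
        return X.values[:, cols]
    if isinstance(X, pd.DataFrame):
        missing = [f for f in posterior.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"prediction input lacks feature {missing[0]!r}")
        return X[posterior.feature_ids].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != posterior.n_features:
        raise ValueError(
            f"expected {posterior.n_features} feature columns, got {X.shape[1]}")
    return X


def predict(posterior: BartPosterior, X) -> Prediction:
    """Posterior predictive probits Phi^{-1}-scale and probabilities for X.

    X may be an aligned ndarray, a DataFrame with named columns, or a
    FeatureTable; columns are matched to the training feature order and an
    unknown/missing column raises an error naming it.
    """
    return Prediction(posterior.predict_probit(_align(posterior, X)))


# ---------------------------------------------------------------------------
# single-move API (exposes the MH mechanics for inspection and testing)
# ---------------------------------------------------------------------------

def sample_tree_move(tree: DecisionTree, X: np.ndarray, residuals: np.ndarray,
                     config: BartConfig, seed: int,
                     likelihood: bool = True):
    """One grow/prune/change MH step on a single tree against residuals.

    Returns (new_tree, accepted, log_ratio, move_name); the original tree is
    returned (as a fresh object) when the proposal is rejected.  Degenerate
    proposals (e.g. a grow with no admissible split) are auto-rejected.
    """
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    r = np.asarray(residuals, dtype=float)
    if len(r) != X.shape[0]:
        raise ValueError("residual vector must align with training samples")
    slots = tree_to_slots(tree, X)
    feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of = slots
    pg, pp, _ = config.proposal_probs
    acc, logr, mtype = _mcmc._single_move(
        feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of,
        X, r, config.alpha_split, config.beta_split, config.sigma_mu ** 2,
        pg, pp, config.min_node, likelihood, seed)
    new_tree = slots_to_tree(feat, thresh, val, left, right)
    return new_tree, bool(acc), float(logr), MOVE_NAMES[int(mtype)]


def _node_stats(X, r, leaf_of, slot_a, slot_b=-99):
    mask = (leaf_of == slot_a) | (leaf_of == slot_b)
    idx = np.where(mask)[0]
    return idx, len(idx), float(r[idx].sum())


def grow_log_ratio(tree: DecisionTree, X, residuals, config: BartConfig,
                   leaf_slot: int, feature: int, threshold: float,
                   likelihood: bool = True) -> float:
    """Log MH ratio of the grow move splitting the given leaf (preorder slot
    index) on (feature, threshold).  Raises if the move is inadmissible."""
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    r = np.asarray(residuals, dtype=float)
    feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of = \
        tree_to_slots(tree, X)
    if feat[leaf_slot] != _mcmc.LEAF:
        raise ValueError("grow target must be a leaf")
    idx, ns, SP = _node_stats(X, r, leaf_of, leaf_slot)
    lmask = X[idx, feature] <= threshold
    nL = int(lmask.sum())
    nR = ns - nL
    if nL < config.min_node or nR < config.min_node:
        raise ValueError("proposed split leaves an undersized child")
    SL = float(r[idx[lmask]].sum())
    nslots = int(meta[0])
    nleaves = int(_mcmc._count_leaves(feat, nslots))
    w2 = int(_mcmc._count_singly(feat, left, right, nslots))
    par = int(parent[leaf_slot])
    if par >= 0:
        sib = right[par] if left[par] == leaf_slot else left[par]
        w2star = w2 + 1 - (1 if feat[sib] == _mcmc.LEAF else 0)
    else:
        w2star = w2 + 1
    pg, pp, _ = config.proposal_probs
    return float(_mcmc._grow_logratio(
        nleaves, w2star, int(dep[leaf_slot]), ns, SP, nL, SL, nR, SP - SL,
        config.alpha_split, config.beta_split, config.sigma_mu ** 2,
        pg, pp, likelihood))


def prune_log_ratio(tree: DecisionTree, X, residuals, config: BartConfig,
                    node_slot: int, likelihood: bool = True) -> float:
    """Log MH ratio of pruning the given singly-internal node (preorder slot)."""
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    r = np.asarray(residuals, dtype=float)
    feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of = \
        tree_to_slots(tree, X)
    if feat[node_slot] < 0:
        raise ValueError("prune target must be internal")
    cl, cr = int(left[node_slot]), int(right[node_slot])
    if feat[cl] != _mcmc.LEAF or feat[cr] != _mcmc.LEAF:
        raise ValueError("prune target must have two leaf children")
    _, nL, SL = _node_stats(X, r, leaf_of, cl)
    _, ns_r, SR = _node_stats(X, r, leaf_of, cr)
    ns = nL + ns_r
    SP = SL + SR
    nslots = int(meta[0])
    nleaves = int(_mcmc._count_leaves(feat, nslots))
    w2 = int(_mcmc._count_singly(feat, left, right, nslots))
    pg, pp, _ = config.proposal_probs
    return float(-_mcmc._grow_logratio(
        nleaves - 1, w2, int(dep[node_slot]), ns, SP, nL, SL, ns - nL, SR,
        config.alpha_split, config.beta_split, config.sigma_mu ** 2,
        pg, pp, likelihood))


def gibbs_leaf_draws(tree: DecisionTree, X, residuals, config: BartConfig,
                     n_draws: int, seed: int) -> np.ndarray:
    """Repeated conjugate draws of all leaf values on a frozen tree.

    Columns are the tree's leaves in preorder; this is exactly the leaf-update
    step the chain performs, exposed so it can be checked against the
    closed-form normal posterior.
    """
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    r = np.asarray(residuals, dtype=float)
    feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of = \
        tree_to_slots(tree, X)
    return _mcmc._gibbs_leaves(feat, val, int(meta[0]), leaf_of, r,
                               X.shape[0], config.sigma_mu ** 2, n_draws, seed)


def prior_split_frequencies(X, config: BartConfig, n_draws: int, seed: int,
                            max_depth: int = 2, n_burn: int = 1000):
    """Empirical P(split at depth d) from a likelihood-free chain.

    Runs the move sampler on a single tree with the likelihood switched off,
    so its stationary law is the tree-structure prior (restricted to splits
    admissible for X), and reports, per depth, the fraction of existing nodes
    that are internal across retained draws.
    """
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    cfg = BartConfig(m=1, n_burn=n_burn, n_post=n_draws,
                     alpha_split=config.alpha_split,
                     beta_split=config.beta_split, k_leaf=config.k_leaf,
                     proposal_probs=config.proposal_probs,
                     min_node=config.min_node, seed=seed)
    y = np.zeros(X.shape[0], dtype=np.int8)
    post = fit_probit_arrays(X, y, [f"x{j}" for j in range(X.shape[1])],
                             cfg, keep_draws=True, prior_only=True)
    splits, nodes = _mcmc._depth_split_stats(
        post.node_feature, post.node_left, post.node_right,
        post.tree_offsets, post.n_draws * post.m, max_depth)
    with np.errstate(invalid="ignore"):
        rates = splits / np.maximum(nodes, 1)
    return rates, splits, nodes
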