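"""Pairwise interaction mining on posterior tree paths.

Two features are counted as co-occurring when they both appear as split rules
on the same root-to-terminal path of a fitted tree; a pair's count is the
number of such paths, summed over every tree of every posterior draw (repeat
splits on the same feature along one path count once).  Feature pairs with
high counts are candidates for interaction effects, because a sum of small
trees only routes a prediction through two features jointly when their
combination carries signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .bart import BartPosterior

logger = logging.getLogger("bartomics")


@dataclass
class InteractionCountMatrix:
    """Symmetric pair co-occurrence counts (zero diagonal) over a posterior."""

    feature_ids: list
    counts: np.ndarray
    n_draws: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        p = len(self.feature_ids)
        if self.counts.shape != (p, p):
            raise ValueError("counts must be a square feature x feature matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal must be zero")

    def normalized(self) -> np.ndarray:
        """Counts per posterior draw (output convenience; storage stays raw)."""
        return self.counts / max(self.n_draws, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids,
                            columns=self.feature_ids)


@dataclass
class InteractionConfig:
    top_fraction: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")


def count_pair_interactions(posterior: BartPosterior) -> InteractionCountMatrix:
    """Count, for every unordered feature pair, the tree paths they share.

    Iterative traversal over the posterior's flat tree blocks: each
    root-to-terminal path contributes one increment to every unordered pair of
    distinct features split on along it.  Stump-only forests give a zero matrix.
    """
    p = posterior.n_features
    if posterior.node_feature.size == 0 and posterior.n_draws > 0:
        raise ValueError("posterior holds no tree draws (fitted with "
                         "keep_draws=False); refit with keep_draws=True")
    counts = np.zeros((p, p), dtype=np.int64)
    nf = posterior.node_feature
    nl = posterior.node_left
    nr = posterior.node_right
    offsets = posterior.tree_offsets
    n_trees = posterior.n_draws * posterior.m

    for k in range(n_trees):
        base = int(offsets[k])
        # stack of (local node, tuple of features on the path so far)
        stack = [(0, ())]
        while stack:
            node, path = stack.pop()
            w = base + node
            j = int(nf[w])
            if j < 0:
                feats = sorted(set(path))
                for a_i in range(len(feats)):
                    for b_i in range(a_i + 1, len(feats)):
                        counts[feats[a_i], feats[b_i]] += 1
                        counts[feats[b_i], feats[a_i]] += 1
                continue
            new_path = path + (j,)
            stack.append((int(nl[w]), new_path))
            stack.append((int(nr[w]), new_path))

    return InteractionCountMatrix(list(posterior.feature_ids), counts,
                                  posterior.n_draws)


def top_pairs(matrix: InteractionCountMatrix,
              config: InteractionConfig = InteractionConfig()) -> pd.DataFrame:
    """Rank all p(p-1)/2 unordered pairs by count and keep the top fraction.

    The cut is ceil(top_fraction * n_pairs) pairs, extended through ties at the
    boundary; ties order lexicographically by feature id for determinism.
    Returns a DataFrame (feature_a, feature_b, count, rank); empty (with a
    warning) when no pair ever co-occurs.
    """
    ids = matrix.feature_ids
    p = len(ids)
    rows = []
    for i, j in combinations(range(p), 2):
        a, b = sorted((ids[i], ids[j]))
        rows.append((a, b, int(matrix.counts[i, j])))
    if not rows or all(c == 0 for _, _, c in rows):
        logger.warning("all-zero interaction matrix; no pairs to rank")
        return pd.DataFrame(columns=["feature_a", "feature_b", "count", "rank"])
    rows.sort(key=lambda t: (-t[2], t[0], t[1]))
    n_pairs = len(rows)
    k = int(np.ceil(config.top_fraction * n_pairs))
    cut_count = rows[k - 1][2]
    while k < n_pairs and rows[k][2] == cut_count:
        k += 1
    out = pd.DataFrame(rows[:k], columns=["feature_a", "feature_b", "count"])
    out["rank"] = np.arange(1, k + 1)
    return out


def pair_rank(matrix: InteractionCountMatrix, feature_a: str,
              feature_b: str) -> int:
    """1-based rank of a pair's count among all unordered pairs (competition
    ranking: rank = 1 + number of pairs with a strictly larger count)."""
    ia = matrix.feature_ids.index(feature_a)
    ib = matrix.feature_ids.index(feature_b)
    target = matrix.counts[ia, ib]
    iu = np.triu_indices(len(matrix.feature_ids), k=1)
    upper = matrix.counts[iu]
    return int((upper > target).sum()) + 1
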