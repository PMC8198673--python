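"""Decision-tree containers for the sum-of-trees model.

``DecisionTree`` is a small recursive structure: an internal node carries a
split feature index and a threshold (samples with value <= threshold go left),
a leaf carries its probit-scale contribution.  ``SumOfTrees`` is one posterior
draw of the ensemble, predicting the sum of its trees' outputs.

These objects are the human-auditable face of the model (hand-built forests in
tests, JSON serialisation); the sampler itself works on the flat arrays in
:mod:`bartomics._mcmc`, and converters between the two live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._mcmc import _CAP, LEAF, UNUSED


@dataclass
class DecisionTree:
    """One regression tree; either a leaf (``leaf_value``) or an internal node
    with ``split_feature``/``split_value`` and two children."""

    split_feature: Optional[int] = None
    split_value: float = 0.0
    left: Optional["DecisionTree"] = None
    right: Optional["DecisionTree"] = None
    leaf_value: float = 0.0

    def __post_init__(self):
        if self.split_feature is not None:
            if self.left is None or self.right is None:
                raise ValueError("internal node must have two children")

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the tree on an (n, p) matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self
            while not node.is_leaf:
                node = node.left if row[node.split_feature] <= node.split_value else node.right
            out[i] = node.leaf_value
        return out

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def leaf_paths(self):
        """Yield the list of split features along every root-to-leaf path."""
        def rec(node, path):
            if node.is_leaf:
                yield list(path)
            else:
                path.append(node.split_feature)
                yield from rec(node.left, path)
                yield from rec(node.right, path)
                path.pop()
        yield from rec(self, [])

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf_value": float(self.leaf_value)}
        return {
            "split_feature": int(self.split_feature),
            "split_value": float(self.split_value),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        if "leaf_value" in d:
            return cls(leaf_value=float(d["leaf_value"]))
        return cls(
            split_feature=int(d["split_feature"]),
            split_value=float(d["split_value"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def leaf(value: float) -> DecisionTree:
    return DecisionTree(leaf_value=value)


def split(feature: int, threshold: float, left: DecisionTree,
          right: DecisionTree) -> DecisionTree:
    return DecisionTree(split_feature=feature, split_value=threshold,
                        left=left, right=right)


def stump(feature: int, threshold: float, left_value: float,
          right_value: float) -> DecisionTree:
    """Single-split tree: value <= threshold -> left_value, else right_value."""
    return split(feature, threshold, leaf(left_value), leaf(right_value))


@dataclass
class SumOfTrees:
    """One posterior draw of the ensemble: f(x) = sum_k T_k(x)."""

    trees: list

    @property
    def m(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict(X)
        return out

    def to_dict(self) -> dict:
        return {"trees": [t.to_dict() for t in self.trees]}

    @classmethod
    def from_dict(cls, d: dict) -> "SumOfTrees":
        return cls(trees=[DecisionTree.from_dict(t) for t in d["trees"]])


# ---------------------------------------------------------------------------
# flat-array conversions
# ---------------------------------------------------------------------------

def tree_to_slots(tree: DecisionTree, X: np.ndarray):
    """Expand a DecisionTree into the sampler's slot arrays plus the leaf
    assignment of every row of ``X``.  Used by the single-move API."""
    if tree.n_nodes() > _CAP:
        raise ValueError("tree exceeds the sampler's node capacity")
    feat = np.full(_CAP, UNUSED, np.int32)
    thresh = np.zeros(_CAP, np.float64)
    val = np.zeros(_CAP, np.float64)
    left = np.full(_CAP, -1, np.int32)
    right = np.full(_CAP, -1, np.int32)
    parent = np.full(_CAP, -1, np.int32)
    dep = np.zeros(_CAP, np.int32)
    counter = [0]

    def assign(node, par, d):
        s = counter[0]
        counter[0] += 1
        parent[s] = par
        dep[s] = d
        if node.is_leaf:
            feat[s] = LEAF
            val[s] = node.leaf_value
        else:
            feat[s] = node.split_feature
            thresh[s] = node.split_value
            left[s] = assign(node.left, s, d + 1)
            right[s] = assign(node.right, s, d + 1)
        return s

    assign(tree, -1, 0)
    n_nodes = counter[0]
    meta = np.array([n_nodes, 0, n_nodes], np.int64)
    freelist = np.zeros(_CAP, np.int32)

    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    leaf_of = np.empty(X.shape[0], np.int32)
    for i, row in enumerate(X):
        s = 0
        while feat[s] >= 0:
            s = left[s] if row[feat[s]] <= thresh[s] else right[s]
        leaf_of[i] = s
    return feat, thresh, val, left, right, parent, dep, meta, freelist, leaf_of


def slots_to_tree(feat, thresh, val, left, right, root=0) -> DecisionTree:
    """Rebuild a DecisionTree from slot arrays (inverse of tree_to_slots)."""
    s = root
    if feat[s] < 0:
        return DecisionTree(leaf_value=float(val[s]))
    return DecisionTree(
        split_feature=int(feat[s]),
        split_value=float(thresh[s]),
        left=slots_to_tree(feat, thresh, val, left, right, left[s]),
        right=slots_to_tree(feat, thresh, val, left, right, right[s]),
    )


def flat_block_to_tree(nf, nth, nv, nl, nr, base) -> DecisionTree:
    """Rebuild a DecisionTree from one serialized tree block (root at ``base``,
    child indices local to the block)."""
    def rec(node):
        w = base + node
        if nf[w] < 0:
            return DecisionTree(leaf_value=float(nv[w]))
        return DecisionTree(split_feature=int(nf[w]), split_value=float(nth[w]),
                            left=rec(int(nl[w])), right=rec(int(nr[w])))
    return rec(0)


def forest_to_flat(forests):
    """Serialize a list of SumOfTrees (equal m) into the flat posterior format.

    Returns (node_feature, node_threshold, node_value, node_left, node_right,
    tree_offsets) matching the layout produced by the sampler.
    """
    if not forests:
        raise ValueError("need at least one draw")
    m = forests[0].m
    if any(fst.m != m for fst in forests):
        raise ValueError("all draws must contain the same number of trees")
    nf, nth, nv, nl, nr = [], [], [], [], []
    offsets = [0]

    def emit(node):
        idx = len(nf)
        if node.is_leaf:
            nf.append(-1)
            nth.append(0.0)
            nv.append(float(node.leaf_value))
            nl.append(-1)
            nr.append(-1)
        else:
            nf.append(int(node.split_feature))
            nth.append(float(node.split_value))
            nv.append(0.0)
            nl.append(-1)
            nr.append(-1)
            li = emit(node.left)
            ri = emit(node.right)
            base = offsets[-1]
            nl[idx] = li - base
            nr[idx] = ri - base
        return idx

    for fst in forests:
        for tree in fst.trees:
            emit(tree)
            offsets.append(len(nf))

    return (np.asarray(nf, np.int32), np.asarray(nth, np.float64),
            np.asarray(nv, np.float64), np.asarray(nl, np.int32),
            np.asarray(nr, np.int32), np.asarray(offsets, np.int64))
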