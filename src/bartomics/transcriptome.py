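"""Bulk-transcriptomics workflow for heavily imbalanced cohorts.

Three pieces:

* **Iterative class-balanced undersampling around a pluggable two-group
  differential test.**  With, say, 459 tumour vs 41 normal samples, the
  majority class is partitioned into floor(459/41) = 11 disjoint blocks; each
  iteration tests one block against the (fully reused) minority class,
  p-values are Benjamini-Hochberg adjusted, and gene lists are formed at a
  decreasing ladder of significance cutoffs.  Per-cutoff unions and the
  across-iteration intersection ("consensus") are reported, with up/down
  direction labels from the sign of the mean log fold change.

* **Recursive feature elimination with union/multiplicity accounting**: per
  undersampled iteration, a ranker (default: BART inclusion proportions) is
  refit and the weakest features dropped until a target size is reached;
  iteration lists are aggregated as a union with multiplicity counts.

* **Gene-list overlap** with per-gene direction concordance, for comparing,
  e.g., bulk against single-cell derived lists.

The default two-group test is a Welch t-test on log2 counts-per-million; the
internals of dedicated differential-expression packages (dispersion
estimation, shrinkage) are deliberately behind the pluggable-test contract.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import stage_seed
from .bart import BartConfig, fit_probit_arrays
from .selection import inclusion_proportions


def log_cpm(counts: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with a +1 pseudo-count (genes x samples)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    return np.log2(counts / lib * 1e6 + 1.0)


def welch_logcpm_test(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Default pluggable test: gene-wise Welch t-test on log2-CPM.

    Returns one p-value per gene; genes with zero variance in both groups get
    p = 1 (no evidence)."""
    la = log_cpm(counts_a)
    lb = log_cpm(counts_b)
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


@dataclass
class DEConfig:
    group_size: int = 41
    cutoff_ladder: Tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)
    adjust_method: str = "bh"
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_logcpm_test
    seed: int = 0

    def __post_init__(self):
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        lad = tuple(self.cutoff_ladder)
        if not lad or any(not 0 < c < 1 for c in lad) \
                or any(b >= a for a, b in zip(lad, lad[1:])):
            raise ValueError("cutoff_ladder must be strictly decreasing in (0, 1)")
        if self.adjust_method.lower() not in ("bh", "fdr_bh"):
            raise ValueError("only Benjamini-Hochberg adjustment is supported")
        self.cutoff_ladder = lad


@dataclass
class GeneListReport:
    """Aggregated gene lists from an iterated procedure."""

    per_iteration: list  # list of gene-id lists (final cutoff / final RFE set)
    union: list  # sorted union across iterations
    multiplicity: dict  # gene -> number of iterations listing it
    consensus: list  # genes present in every iteration (sorted)
    directions: dict = field(default_factory=dict)  # gene -> up/down/flat
    per_cutoff_union: Optional[dict] = None  # cutoff -> sorted union
    per_cutoff_consensus: Optional[dict] = None  # cutoff -> sorted intersection
    n_iterations: int = 0

    def __post_init__(self):
        if not set(self.consensus) <= set(self.union):
            raise ValueError("consensus must be a subset of the union")

    @property
    def recurrent(self) -> list:
        """Genes appearing in more than one iteration."""
        return sorted(g for g, c in self.multiplicity.items() if c > 1)

    def direction_summary(self) -> dict:
        up = sum(1 for g in self.consensus if self.directions.get(g) == "up")
        down = sum(1 for g in self.consensus if self.directions.get(g) == "down")
        return {"up": up, "down": down,
                "flat": len(self.consensus) - up - down}


def _undersample_blocks(labels: np.ndarray, group_size: int, seed: int):
    """Disjoint majority-class blocks + per-iteration minority draws.

    Majority samples are shuffled once and split into floor(majority/group_size)
    disjoint blocks (never reused across iterations); the minority class is
    reused in full when its size equals group_size, otherwise freshly
    subsampled (without replacement within an iteration).
    """
    labels = np.asarray(labels)
    idx0 = np.where(labels == 0)[0]
    idx1 = np.where(labels == 1)[0]
    if min(len(idx0), len(idx1)) < group_size:
        raise ValueError(
            f"group_size {group_size} exceeds a class size "
            f"({len(idx0)} vs {len(idx1)})")
    minority, majority = (idx1, idx0) if len(idx1) < len(idx0) else (idx0, idx1)
    n_iter = len(majority) // group_size
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(majority)
    blocks = [shuffled[k * group_size:(k + 1) * group_size]
              for k in range(n_iter)]
    minor_draws = []
    for k in range(n_iter):
        if len(minority) == group_size:
            minor_draws.append(minority.copy())
        else:
            minor_draws.append(rng.choice(minority, size=group_size,
                                          replace=False))
    return blocks, minor_draws, labels[minority[0]]


def undersample_union_de(counts: pd.DataFrame, labels: np.ndarray,
                         config: DEConfig) -> GeneListReport:
    """Iterated undersampled differential testing with a cutoff ladder.

    ``counts`` is genes x samples (raw counts).  Per iteration the plugged
    test compares the class-0 submatrix against class-1, p-values are
    BH-adjusted, and gene sets are taken at every ladder cutoff.  The report
    carries per-cutoff unions and intersections across iterations; the
    headline ``consensus`` uses the final (smallest) cutoff.
    """
    genes = list(counts.index)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in the count matrix")
    C = counts.to_numpy(dtype=float)
    labels = np.asarray(labels)
    blocks, minor_draws, _ = _undersample_blocks(labels, config.group_size,
                                                 stage_seed(config.seed, "de-blocks"))
    idx0_all = np.where(labels == 0)[0]
    idx1_all = np.where(labels == 1)[0]
    minority_is_1 = len(idx1_all) < len(idx0_all)

    per_iter_sets = {c: [] for c in config.cutoff_ladder}
    lfc_sum = np.zeros(len(genes))
    final_cut = config.cutoff_ladder[-1]
    for block, minor in zip(blocks, minor_draws):
        if minority_is_1:
            a, b = C[:, block], C[:, minor]  # a = class 0, b = class 1
        else:
            a, b = C[:, minor], C[:, block]
        p = np.asarray(config.test(a, b), dtype=float)
        if p.shape != (len(genes),):
            raise ValueError("test must return one p-value per gene")
        if not np.isfinite(p).all():
            bad = [genes[i] for i in np.where(~np.isfinite(p))[0][:5]]
            raise ValueError(f"test returned non-finite p-values for {bad}")
        padj = bh_adjust(p)
        lfc_sum += log_cpm(b).mean(axis=1) - log_cpm(a).mean(axis=1)
        for c in config.cutoff_ladder:
            per_iter_sets[c].append({genes[i] for i in np.where(padj < c)[0]})

    n_iter = len(blocks)
    per_cut_union = {c: sorted(set().union(*s)) for c, s in per_iter_sets.items()}
    per_cut_cons = {c: sorted(set.intersection(*s)) if s else []
                    for c, s in per_iter_sets.items()}
    mult = Counter()
    for s in per_iter_sets[final_cut]:
        mult.update(s)
    mean_lfc = lfc_sum / n_iter
    directions = {}
    for g in per_cut_union[max(config.cutoff_ladder)]:
        v = mean_lfc[genes.index(g)]
        directions[g] = "up" if v > 0 else ("down" if v < 0 else "flat")
    return GeneListReport(
        per_iteration=[sorted(s) for s in per_iter_sets[final_cut]],
        union=per_cut_union[final_cut],
        multiplicity=dict(mult),
        consensus=per_cut_cons[final_cut],
        directions=directions,
        per_cutoff_union=per_cut_union,
        per_cutoff_consensus=per_cut_cons,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

def bart_inclusion_ranker(bart_config: Optional[BartConfig] = None,
                          seed: int = 0) -> Callable:
    """Default RFE ranker: probit BART inclusion proportions as importances."""
    base = bart_config or BartConfig(m=20, n_burn=50, n_post=100)

    def ranker(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        cfg = BartConfig(**{**base.to_dict(), "seed": seed})
        ids = [f"f{j}" for j in range(X.shape[1])]
        post = fit_probit_arrays(X, y, ids, cfg, keep_draws=False)
        return inclusion_proportions(post).proportions

    return ranker


def _rfe_one(X: np.ndarray, y: np.ndarray, genes: list, ranker: Callable,
             step, n_select: int) -> list:
    keep = list(range(len(genes)))
    while len(keep) > n_select:
        scores = np.asarray(ranker(X[:, keep], y), dtype=float)
        if len(scores) != len(keep):
            raise ValueError("ranker must score every remaining feature")
        if isinstance(step, float) and 0 < step < 1:
            n_drop = max(1, int(math.floor(step * len(keep))))
        else:
            n_drop = max(1, int(step))
        n_drop = min(n_drop, len(keep) - n_select)
        # drop the weakest, deterministic tie-break by original order
        order = np.lexsort((np.arange(len(keep)), scores))
        drop = set(order[:n_drop])
        keep = [k for i, k in enumerate(keep) if i not in drop]
    return [genes[k] for k in keep]


def rfe_union(expr: pd.DataFrame, labels: np.ndarray,
              ranker: Optional[Callable] = None, step=1,
              config: Optional[DEConfig] = None,
              n_select: int = 10) -> GeneListReport:
    """Recursive feature elimination per undersampled iteration.

    ``expr`` is genes x samples (e.g. the consensus-gene submatrix); per
    iteration (same disjoint-majority undersampling scheme as the DE stage,
    shared by seed) the ranker is refit and the lowest-ranked ``step`` features
    (count, or fraction of the remainder if a float < 1) are eliminated until
    ``n_select`` remain.  Iteration lists are aggregated as union +
    multiplicity; ``recurrent`` gives the genes appearing more than once.
    """
    config = config or DEConfig()
    genes = list(expr.index)
    if n_select >= len(genes):
        raise ValueError("target size must be smaller than the feature count")
    ranker = ranker or bart_inclusion_ranker(seed=stage_seed(config.seed, "rfe-ranker"))
    C = expr.to_numpy(dtype=float)
    labels = np.asarray(labels)
    blocks, minor_draws, _ = _undersample_blocks(labels, config.group_size,
                                                 stage_seed(config.seed, "de-blocks"))
    per_iter = []
    for block, minor in zip(blocks, minor_draws):
        idx = np.concatenate([block, minor])
        X = log_cpm(C[:, idx]).T  # samples x genes on a stabilised scale
        y = labels[idx]
        per_iter.append(sorted(_rfe_one(X, y, genes, ranker, step, n_select)))
    mult = Counter()
    for s in per_iter:
        mult.update(s)
    union = sorted(set().union(*per_iter)) if per_iter else []
    consensus = sorted(set.intersection(*map(set, per_iter))) if per_iter else []
    return GeneListReport(per_iteration=per_iter, union=union,
                          multiplicity=dict(mult), consensus=consensus,
                          n_iterations=len(per_iter))


# ---------------------------------------------------------------------------
# list overlap
# ---------------------------------------------------------------------------

def overlap_gene_lists(list_a, list_b) -> pd.DataFrame:
    """Intersection of two (gene, direction) lists with concordance flags.

    Inputs are sequences of (gene, direction) pairs or dicts gene -> direction;
    duplicate gene ids within one list are an error.  Returns a DataFrame with
    columns gene, direction_a, direction_b, concordant, sorted by gene.
    """
    def as_dict(lst, name):
        if isinstance(lst, dict):
            return dict(lst)
        d = {}
        for g, direction in lst:
            if g in d:
                raise ValueError(f"duplicate gene id {g!r} in {name}")
            d[g] = direction
        return d

    da = as_dict(list_a, "list_a")
    db = as_dict(list_b, "list_b")
    common = sorted(set(da) & set(db))
    return pd.DataFrame({
        "gene": common,
        "direction_a": [da[g] for g in common],
        "direction_b": [db[g] for g in common],
        "concordant": [da[g] == db[g] for g in common],
    })
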