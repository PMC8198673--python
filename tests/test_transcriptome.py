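import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bartomics as bo
from bartomics.transcriptome import _undersample_blocks, bh_adjust, log_cpm


def brute_force_bh(p):
    """Step-up oracle: q_i = min_{j >= i} min(1, p_(j) * n / j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_bh_matches_step_up_oracle(pvals):
    p = np.array(pvals)
    assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_log_cpm_normalises_depth():
    counts = np.array([[10.0, 100.0], [90.0, 900.0]])
    lc = log_cpm(counts)
    assert np.allclose(lc[:, 0], lc[:, 1])  # same composition, 10x depth


def test_de_config_validation():
    with pytest.raises(ValueError):
        bo.DEConfig(group_size=1)
    with pytest.raises(ValueError):
        bo.DEConfig(cutoff_ladder=(0.01, 0.05))  # not decreasing
    with pytest.raises(ValueError):
        bo.DEConfig(cutoff_ladder=())
    with pytest.raises(ValueError):
        bo.DEConfig(cutoff_ladder=(1.5,))
    with pytest.raises(ValueError):
        bo.DEConfig(adjust_method="bonferroni")


def test_undersample_blocks_disjoint_cover():
    labels = np.array([1] * 41 + [0] * 459)
    blocks, minors, _ = _undersample_blocks(labels, 41, seed=0)
    assert len(blocks) == 11  # floor(459 / 41)
    flat = np.concatenate(blocks)
    assert len(flat) == len(set(flat)) == 451  # disjoint majority blocks
    assert all(labels[b].sum() == 0 for b in blocks)
    # minority equals group size -> reused in full every iteration
    for m in minors:
        assert sorted(m) == list(range(41))


def test_undersample_blocks_subsamples_large_minority():
    labels = np.array([0] * 50 + [1] * 30)
    blocks, minors, _ = _undersample_blocks(labels, 20, seed=1)
    assert len(blocks) == 2
    for m in minors:
        assert len(m) == len(set(m)) == 20
        assert labels[m].sum() == 20
    with pytest.raises(ValueError, match="class size"):
        _undersample_blocks(labels, 40, seed=0)


@pytest.fixture(scope="module")
def de_data():
    counts, labels = bo.simulate_counts(
        120, 120, 24, fold_changes={"G0001": 6.0, "G0002": 0.15}, seed=8)
    return counts, labels


def test_undersample_union_de_structure(de_data):
    counts, labels = de_data
    cfg = bo.DEConfig(group_size=24, seed=3)
    rep = bo.undersample_union_de(counts, labels, cfg)
    assert rep.n_iterations == 5
    assert len(rep.per_iteration) == 5
    # ladder nesting: stricter cutoffs give subset unions
    lad = cfg.cutoff_ladder
    for a, b in zip(lad, lad[1:]):
        assert set(rep.per_cutoff_union[b]) <= set(rep.per_cutoff_union[a])
        assert set(rep.per_cutoff_consensus[b]) \
            <= set(rep.per_cutoff_consensus[a])
    assert set(rep.consensus) <= set(rep.union)
    # consensus = genes hit in every iteration at the final cutoff
    assert rep.consensus == sorted(
        g for g, c in rep.multiplicity.items() if c == 5)
    assert {"G0001", "G0002"} <= set(rep.consensus)
    assert rep.directions["G0001"] == "up"
    assert rep.directions["G0002"] == "down"
    summary = rep.direction_summary()
    assert summary["up"] + summary["down"] + summary["flat"] \
        == len(rep.consensus)


def test_undersample_de_errors(de_data):
    counts, labels = de_data
    dup = pd.concat([counts.iloc[:2], counts.iloc[:2]])
    with pytest.raises(ValueError, match="duplicate"):
        bo.undersample_union_de(dup, labels, bo.DEConfig(group_size=24))

    def bad_test(a, b):
        return np.array([0.5])

    with pytest.raises(ValueError, match="per gene"):
        bo.undersample_union_de(counts, labels,
                                bo.DEConfig(group_size=24, test=bad_test))


def test_report_validation():
    with pytest.raises(ValueError, match="subset"):
        bo.GeneListReport(per_iteration=[["a"]], union=["a"],
                          multiplicity={"a": 1}, consensus=["b"])


# --- RFE ---------------------------------------------------------------------

def test_rfe_with_deterministic_ranker(de_data):
    counts, labels = de_data
    sub = counts.iloc[:8]

    def ranker(X, y):
        # favour genes whose column mean is largest -- deterministic proxy
        return X.mean(axis=0)

    rep = bo.rfe_union(sub, labels, ranker=ranker, step=2,
                       config=bo.DEConfig(group_size=24, seed=1), n_select=3)
    assert rep.n_iterations == 5
    for lst in rep.per_iteration:
        assert len(lst) == 3
    assert set(rep.union) == set().union(*map(set, rep.per_iteration))
    assert rep.recurrent == sorted(g for g, c in rep.multiplicity.items()
                                   if c > 1)


def test_rfe_step_fraction_and_validation(de_data):
    counts, labels = de_data
    sub = counts.iloc[:10]

    def ranker(X, y):
        return np.arange(X.shape[1], dtype=float)

    rep = bo.rfe_union(sub, labels, ranker=ranker, step=0.5,
                       config=bo.DEConfig(group_size=24, seed=2), n_select=2)
    for lst in rep.per_iteration:
        assert len(lst) == 2
    with pytest.raises(ValueError, match="target size"):
        bo.rfe_union(sub, labels, ranker=ranker, n_select=10,
                     config=bo.DEConfig(group_size=24))

    def bad_ranker(X, y):
        return np.zeros(1)

    with pytest.raises(ValueError, match="every remaining"):
        bo.rfe_union(sub, labels, ranker=bad_ranker, n_select=2,
                     config=bo.DEConfig(group_size=24))


def test_bart_ranker_scores_every_feature():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 6))
    y = (X[:, 0] > 0).astype(int)
    ranker = bo.bart_inclusion_ranker(
        bo.BartConfig(m=5, n_burn=20, n_post=30), seed=1)
    scores = ranker(X, y)
    assert scores.shape == (6,)
    assert scores.argmax() == 0  # the informative feature dominates


# --- overlap -----------------------------------------------------------------

def test_overlap_exact_sets_and_directions():
    a = [("g1", "up"), ("g2", "down"), ("g3", "up")]
    b = [("g2", "down"), ("g3", "down"), ("g4", "up")]
    out = bo.overlap_gene_lists(a, b)
    assert list(out["gene"]) == ["g2", "g3"]
    assert list(out["concordant"]) == [True, False]
    empty = bo.overlap_gene_lists(a, [("zz", "up")])
    assert empty.empty


def test_overlap_duplicate_error():
    with pytest.raises(ValueError, match="g1"):
        bo.overlap_gene_lists([("g1", "up"), ("g1", "down")], [("g1", "up")])
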