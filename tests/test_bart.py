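import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

import bartomics as bo
from bartomics.bart import (gibbs_leaf_draws, grow_log_ratio, prune_log_ratio,
                            sample_tree_move)


def test_config_validation():
    for kw in [{"m": 0}, {"n_post": 0}, {"alpha_split": 1.0},
               {"beta_split": -1.0}, {"k_leaf": 0.0}, {"min_node": 0},
               {"proposal_probs": (0.5, 0.5, 0.5)}]:
        with pytest.raises(ValueError):
            bo.BartConfig(**kw)


def test_sigma_mu_formula():
    cfg = bo.BartConfig(m=25, k_leaf=2.0)
    assert cfg.sigma_mu == pytest.approx(3.0 / (2.0 * 5.0))


def test_config_dict_round_trip():
    cfg = bo.BartConfig(m=7, n_burn=11, n_post=13, seed=5)
    assert bo.BartConfig.from_dict(cfg.to_dict()) == cfg


def test_offset_is_probit_of_case_fraction(small_cohort, small_posterior):
    ybar = small_cohort.outcome.mean()
    assert small_posterior.offset == pytest.approx(ndtri(ybar))


def test_fit_requires_both_classes():
    X = np.random.default_rng(0).normal(size=(20, 3))
    with pytest.raises(ValueError, match="both classes"):
        bo.fit_probit_arrays(X, np.zeros(20, int), ["a", "b", "c"],
                             bo.BartConfig(m=2, n_burn=5, n_post=5))


def test_fit_deterministic_per_seed(small_cohort):
    cfg = bo.BartConfig(m=5, n_burn=20, n_post=20, seed=3)
    a = bo.fit_probit(small_cohort, cfg)
    b = bo.fit_probit(small_cohort, cfg)
    assert np.array_equal(a.node_feature, b.node_feature)
    assert np.array_equal(a.node_threshold, b.node_threshold)
    c = bo.fit_probit(small_cohort, bo.BartConfig(m=5, n_burn=20, n_post=20,
                                                  seed=4))
    assert not np.array_equal(a.node_value, c.node_value)


def test_fit_learns_planted_effect(small_cohort, small_posterior):
    prob = bo.predict(small_posterior, small_cohort).prob_mean
    y = small_cohort.outcome
    assert prob[y == 1].mean() > prob[y == 0].mean() + 0.2
    acc = ((prob > 0.5).astype(int) == y).mean()
    assert acc > 0.7


def test_predict_matches_materialized_draws(small_cohort, small_posterior):
    X = small_cohort.values[:8]
    fast = small_posterior.predict_probit(X)
    slow = np.array([f.predict(X) for f in small_posterior.draws]) \
        + small_posterior.offset
    assert np.allclose(fast, slow, atol=1e-12)


def test_predict_input_alignment(small_cohort, small_posterior):
    df = small_cohort.to_frame().drop(columns="outcome")
    shuffled = df[df.columns[::-1]]
    a = bo.predict(small_posterior, df).prob_mean
    b = bo.predict(small_posterior, shuffled).prob_mean
    c = bo.predict(small_posterior, small_cohort).prob_mean
    assert np.allclose(a, b) and np.allclose(a, c)
    with pytest.raises(KeyError, match="M1"):
        bo.predict(small_posterior, df.drop(columns="M1"))
    with pytest.raises(ValueError, match="feature columns"):
        bo.predict(small_posterior, np.zeros((2, 3)))


def test_prob_draws_are_probit_transform(small_cohort, small_posterior):
    pred = bo.predict(small_posterior, small_cohort.values[:5])
    assert np.allclose(pred.prob_draws, ndtr(pred.probit_draws))
    assert ((pred.prob_mean >= 0) & (pred.prob_mean <= 1)).all()


def test_posterior_json_round_trip(small_cohort):
    cfg = bo.BartConfig(m=4, n_burn=10, n_post=8, seed=2)
    post = bo.fit_probit(small_cohort, cfg)
    post2 = bo.BartPosterior.from_json(post.to_json())
    X = small_cohort.values[:10]
    assert np.allclose(post.predict_probit(X), post2.predict_probit(X))
    assert post2.config == cfg
    assert post2.feature_ids == post.feature_ids


def test_constant_column_warns(caplog):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 3))
    X[:, 1] = 7.0
    y = (rng.random(30) < 0.5).astype(int)
    with caplog.at_level("WARNING", logger="bartomics"):
        post = bo.fit_probit_arrays(X, y, ["a", "const", "c"],
                                    bo.BartConfig(m=3, n_burn=20, n_post=30))
    assert "const" in caplog.text
    assert post.split_counts[1] == 0


# --- MH move mechanics -------------------------------------------------------

def _toy_data(seed=0, n=40, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    r = rng.normal(size=n) * 0.5
    return X, r


def test_grow_prune_detailed_balance():
    """The log MH ratio of a grow move and of the prune move that reverses it
    must be exact negatives (the ratios are reciprocal by detailed balance)."""
    X, r = _toy_data()
    cfg = bo.BartConfig(m=1, min_node=2)
    g = grow_log_ratio(bo.leaf(0.0), X, r, cfg, leaf_slot=0, feature=1,
                       threshold=float(np.median(X[:, 1])))
    grown = bo.stump(1, float(np.median(X[:, 1])), 0.0, 0.0)
    p = prune_log_ratio(grown, X, r, cfg, node_slot=0)
    assert g == pytest.approx(-p, abs=1e-10)


def test_grow_prune_detailed_balance_deep():
    X, r = _toy_data(seed=3)
    cfg = bo.BartConfig(m=1, min_node=1)
    base = bo.split(0, 0.0, bo.leaf(0.1), bo.leaf(-0.1))
    # grow the left leaf (preorder slot 1) on feature 2
    thr = float(np.median(X[X[:, 0] <= 0.0, 2]))
    g = grow_log_ratio(base, X, r, cfg, leaf_slot=1, feature=2, threshold=thr)
    grown = bo.split(0, 0.0, bo.stump(2, thr, 0.0, 0.0), bo.leaf(-0.1))
    p = prune_log_ratio(grown, X, r, cfg, node_slot=1)
    assert g == pytest.approx(-p, abs=1e-10)


def test_grow_validation():
    X, r = _toy_data()
    cfg = bo.BartConfig(m=1, min_node=30)
    with pytest.raises(ValueError, match="undersized"):
        grow_log_ratio(bo.leaf(0.0), X, r, cfg, 0, 0, 0.0)
    with pytest.raises(ValueError, match="leaf"):
        grow_log_ratio(bo.stump(0, 0.0, 0.0, 0.0), X, r,
                       bo.BartConfig(m=1), 0, 0, 0.0)
    with pytest.raises(ValueError, match="internal"):
        prune_log_ratio(bo.leaf(0.0), X, r, bo.BartConfig(m=1), 0)


def test_sample_tree_move_keeps_tree_valid():
    X, r = _toy_data(seed=5, n=60)
    cfg = bo.BartConfig(m=1, min_node=2)
    tree = bo.leaf(0.0)
    n_accepted = 0
    for step in range(60):
        new_tree, accepted, logr, move = sample_tree_move(tree, X, r, cfg,
                                                          seed=step)
        assert move in {"grow", "prune", "change"}
        if accepted:
            n_accepted += 1
            tree = new_tree
        else:
            assert new_tree.to_dict() == tree.to_dict()
        # structural sanity at every step
        assert tree.depth() <= 12
    assert n_accepted > 0


def test_prune_on_stump_gives_root_leaf():
    X, r = _toy_data(seed=6)
    cfg = bo.BartConfig(m=1, min_node=2)
    tree = bo.stump(0, 0.0, 0.3, -0.3)
    for step in range(200):
        new_tree, accepted, _, move = sample_tree_move(tree, X, r, cfg,
                                                       seed=step)
        if accepted and move == "prune":
            assert new_tree.is_leaf
            return
    pytest.fail("no prune accepted in 200 attempts")


# --- conjugate leaf sampling -------------------------------------------------

def test_gibbs_leaf_draws_match_closed_form():
    X, r = _toy_data(seed=7, n=200)
    cfg = bo.BartConfig(m=1, k_leaf=2.0)
    sm2 = cfg.sigma_mu ** 2
    tree = bo.stump(0, 0.0, 0.0, 0.0)
    draws = gibbs_leaf_draws(tree, X, r, cfg, n_draws=4000, seed=1)
    assert draws.shape == (4000, 2)
    left = X[:, 0] <= 0.0
    for col, mask in ((0, left), (1, ~left)):
        n, S = mask.sum(), r[mask].sum()
        post_mean = S / (n + 1.0 / sm2)
        post_sd = 1.0 / np.sqrt(n + 1.0 / sm2)
        mc_se = post_sd / np.sqrt(4000)
        assert abs(draws[:, col].mean() - post_mean) < 4 * mc_se
        assert draws[:, col].std() == pytest.approx(post_sd, rel=0.1)
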