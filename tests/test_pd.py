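import numpy as np
import pytest

import bartomics as bo
from bartomics.cohort import METABOLOME, FeatureTable


def make_table(X, ids=None):
    n, p = X.shape
    ids = ids or [f"M{j + 1}" for j in range(p)]
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=ids,
        layers=np.array([METABOLOME] * p, dtype=object),
        values=X,
        outcome=np.array([0, 1] * (n // 2) + [0] * (n % 2)),
    )


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(0)
    return make_table(rng.uniform(0.5, 4.0, size=(30, 3)))


def brute_force_pd(posterior, table, features, points):
    """Oracle: for each draw and eval point, clamp and average predictions."""
    out = np.empty((len(points), posterior.n_draws))
    cols = [table.column(f) for f in features]
    for k, pt in enumerate(points):
        X = table.values.copy()
        for c, v in zip(cols, np.atleast_1d(pt)):
            X[:, c] = v
        for d, forest in enumerate(posterior.draws):
            out[k, d] = forest.predict(X).mean() + posterior.offset
    return out


def test_stump_pd_is_its_step_function(toy_table):
    post = bo.BartPosterior.from_forests(
        [bo.SumOfTrees([bo.stump(0, 2.0, -1.0, 1.0)])],
        toy_table.feature_ids, offset=0.0)
    s = bo.pd_1d(post, toy_table, "M1", values=[1.0, 2.0, 3.0])
    assert np.array_equal(s.probit_draws[:, 0], [-1.0, -1.0, 1.0])


def test_pd1d_matches_brute_force_oracle(toy_table):
    cfg = bo.BartConfig(m=4, n_burn=20, n_post=10, seed=1)
    post = bo.fit_probit(toy_table, cfg)
    pts = [0.8, 1.5, 2.5]
    s = bo.pd_1d(post, toy_table, "M2", values=pts)
    oracle = brute_force_pd(post, toy_table, ["M2"], pts)
    assert np.allclose(s.probit_draws, oracle, atol=1e-10)


def test_pd2d_matches_brute_force_oracle(toy_table):
    cfg = bo.BartConfig(m=3, n_burn=20, n_post=8, seed=2)
    post = bo.fit_probit(toy_table, cfg)
    s = bo.pd_2d(post, toy_table, ("M1", "M3"), grid_size=4)
    oracle = brute_force_pd(post, toy_table, ["M1", "M3"], s.eval_points)
    assert np.allclose(s.probit_draws, oracle, atol=1e-10)
    assert s.grid_shape == (4, 4)
    assert s.log_odds_grid().shape == (4, 4)
    # corners sit exactly on observed ranges
    col = toy_table.values[:, 0]
    assert s.eval_points[:, 0].min() == col.min()
    assert s.eval_points[:, 0].max() == col.max()


def test_additive_forest_pd2d_decomposes(toy_table):
    """On a forest additive in two features, PD2d(a, b) - PD1d(a) - PD1d(b)
    is constant across the grid (within each draw) to 1e-10."""
    forest = bo.SumOfTrees([bo.stump(0, 2.0, -1.0, 1.0),
                            bo.stump(2, 1.5, 0.5, -0.5),
                            bo.leaf(0.2)])
    post = bo.BartPosterior.from_forests([forest, forest],
                                         toy_table.feature_ids, offset=0.3)
    s2 = bo.pd_2d(post, toy_table, ("M1", "M3"), grid_size=5)
    a_vals = np.unique(s2.eval_points[:, 0])
    b_vals = np.unique(s2.eval_points[:, 1])
    s1a = bo.pd_1d(post, toy_table, "M1", values=a_vals)
    s1b = bo.pd_1d(post, toy_table, "M3", values=b_vals)
    grid2 = s2.probit_draws[:, 0].reshape(5, 5)
    resid = grid2 - s1a.probit_draws[:, 0][:, None] \
        - s1b.probit_draws[:, 0][None, :]
    assert np.ptp(resid) < 1e-10


def test_log_odds_zero_at_probit_zero(toy_table):
    post = bo.BartPosterior.from_forests(
        [bo.SumOfTrees([bo.stump(0, 2.0, 0.0, 1.0)])],
        toy_table.feature_ids, offset=0.0)
    s = bo.pd_1d(post, toy_table, "M1", values=[1.0])
    assert s.mean_probit[0] == 0.0
    assert s.log_odds[0] == 0.0


def test_credible_interval_brackets_mean(toy_table):
    cfg = bo.BartConfig(m=3, n_burn=15, n_post=30, seed=3)
    post = bo.fit_probit(toy_table, cfg)
    s = bo.pd_1d(post, toy_table, "M1")
    lo, hi = s.credible_interval(0.9)
    assert (lo <= s.mean_probit).all() and (s.mean_probit <= hi).all()
    assert len(s.eval_points) == 19  # default 0.05..0.95 quantile grid


def test_pd_validation(toy_table):
    post = bo.BartPosterior.from_forests(
        [bo.SumOfTrees([bo.leaf(0.0)])], toy_table.feature_ids)
    with pytest.raises(KeyError, match="nope"):
        bo.pd_1d(post, toy_table, "nope")
    with pytest.raises(ValueError, match="quantiles"):
        bo.pd_1d(post, toy_table, "M1", quantiles=[-0.1, 0.5])
    with pytest.raises(ValueError, match="grid_size"):
        bo.pd_2d(post, toy_table, ("M1", "M2"), grid_size=1)
    const = make_table(np.column_stack([np.full(10, 2.0),
                                        np.linspace(1, 2, 10)]),
                       ids=["c", "v"])
    post2 = bo.BartPosterior.from_forests(
        [bo.SumOfTrees([bo.leaf(0.0)])], ["c", "v"])
    with pytest.raises(ValueError, match="'c'"):
        bo.pd_2d(post2, const, ("c", "v"))


def test_surface_frame_columns(toy_table):
    post = bo.BartPosterior.from_forests(
        [bo.SumOfTrees([bo.stump(0, 2.0, -1.0, 1.0)])],
        toy_table.feature_ids)
    df = bo.surface_frame(bo.pd_1d(post, toy_table, "M1"))
    assert list(df.columns) == ["M1", "quantile", "mean_probit", "lo", "hi",
                                "log_odds"]
    df2 = bo.surface_frame(bo.pd_2d(post, toy_table, ("M1", "M2"),
                                    grid_size=3))
    assert list(df2.columns) == ["M1", "M2", "mean_probit", "lo", "hi",
                                 "log_odds"]
    assert len(df2) == 9
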