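import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bartomics as bo
from bartomics.cohort import _calibrate_intercept, transformed_standardized
from scipy.special import ndtr


def test_defaults_match_design():
    spec = bo.CohortSpec()
    assert (spec.n_controls, spec.n_cases) == (102, 36)
    assert spec.n_samples == 138


@pytest.mark.parametrize("kwargs", [
    {"n_controls": 0}, {"n_cases": 0}, {"n_taxa": 0},
    {"zero_inflation": 1.5}, {"sequencing_depth": 0.0}, {"dispersion": -1.0},
])
def test_spec_validation(kwargs):
    with pytest.raises(ValueError):
        bo.CohortSpec(**kwargs)


def test_simulate_structure_and_exact_class_counts():
    spec = bo.CohortSpec(n_controls=25, n_cases=15, n_taxa=6, n_metabolites=5,
                         seed=4)
    t = bo.simulate_cohort(spec)
    assert t.n_samples == 40
    assert t.feature_ids[:6] == [f"OTU{i}" for i in range(1, 7)]
    assert t.feature_ids[6:11] == [f"M{i}" for i in range(1, 6)]
    assert t.feature_ids[11:] == ["age", "sex"]
    assert int(t.outcome.sum()) == 15
    mic = t.layers == bo.MICROBIOME
    assert (t.values[:, mic] >= 0).all()
    assert (t.values[:, mic] == np.round(t.values[:, mic])).all()
    met = t.layers == bo.METABOLOME
    assert (t.values[:, met] > 0).all()
    age = t.values[:, t.column("age")]
    assert ((age >= 30) & (age <= 80)).all()
    assert set(np.unique(t.values[:, t.column("sex")])) <= {0.0, 1.0}


def test_simulate_deterministic_per_seed():
    spec = bo.CohortSpec(n_controls=20, n_cases=10, n_taxa=5, n_metabolites=4,
                         seed=9)
    a = bo.simulate_cohort(spec)
    b = bo.simulate_cohort(spec)
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.outcome, b.outcome)
    c = bo.simulate_cohort(bo.CohortSpec(n_controls=20, n_cases=10, n_taxa=5,
                                         n_metabolites=4, seed=10))
    assert not np.array_equal(a.values, c.values)


def test_unknown_effect_feature_raises():
    with pytest.raises(KeyError, match="NOPE"):
        bo.simulate_cohort(bo.CohortSpec(main_effects=(("NOPE", 1.0),)))
    with pytest.raises(KeyError, match="XX"):
        bo.simulate_cohort(bo.CohortSpec(
            interaction_effects=(("M1", "XX", 1.0),)))


def test_planted_effect_shifts_cases():
    spec = bo.CohortSpec(n_controls=60, n_cases=60, n_taxa=5, n_metabolites=5,
                         main_effects=(("M1", 2.0),), seed=2)
    t = bo.simulate_cohort(spec)
    z = transformed_standardized(t)[:, t.column("M1")]
    assert z[t.outcome == 1].mean() > z[t.outcome == 0].mean() + 0.5


def test_transform_standardizes():
    t = bo.simulate_cohort(bo.CohortSpec(n_controls=30, n_cases=20, seed=1))
    Z = transformed_standardized(t)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
    sd = Z.std(axis=0)
    assert np.allclose(sd[sd > 0], 1.0, atol=1e-9)


def test_calibrated_intercept_matches_expected_cases():
    rng = np.random.default_rng(0)
    eta = rng.normal(size=500)
    c = _calibrate_intercept(eta, 120)
    assert abs(ndtr(c + eta).sum() - 120) < 1e-6


@given(st.integers(0, 10_000), st.integers(5, 25), st.integers(5, 25))
@settings(max_examples=15, deadline=None)
def test_cohort_properties(seed, n0, n1):
    spec = bo.CohortSpec(n_controls=n0, n_cases=n1, n_taxa=4, n_metabolites=3,
                         include_covariates=False, seed=seed)
    t = bo.simulate_cohort(spec)
    assert int(t.outcome.sum()) == n1
    assert t.n_features == 7
    assert not np.isnan(t.values).any()


# --- FeatureTable invariants -------------------------------------------------

def make_table(**over):
    kw = dict(sample_ids=["a", "b"], feature_ids=["x", "y"],
              layers=np.array([bo.METABOLOME, bo.METABOLOME], dtype=object),
              values=np.array([[1.0, 2.0], [3.0, 4.0]]),
              outcome=np.array([0, 1]))
    kw.update(over)
    return bo.FeatureTable(**kw)


def test_table_validation():
    with pytest.raises(ValueError, match="unique"):
        make_table(feature_ids=["x", "x"])
    with pytest.raises(ValueError, match="binary"):
        make_table(outcome=np.array([0, 2]))
    with pytest.raises(ValueError, match="layer"):
        make_table(layers=np.array(["bogus", "bogus"], dtype=object))
    with pytest.raises(ValueError, match="positive"):
        make_table(values=np.array([[0.0, 2.0], [3.0, 4.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        make_table(layers=np.array([bo.MICROBIOME, bo.METABOLOME],
                                   dtype=object),
                   values=np.array([[-1.0, 2.0], [3.0, 4.0]]))
    with pytest.raises(ValueError, match="missing"):
        make_table(values=np.array([[np.nan, 2.0], [3.0, 4.0]]))
    with pytest.raises(KeyError, match="zz"):
        make_table().column("zz")


def test_table_subsetting():
    t = make_table()
    sub = t.take([1])
    assert sub.sample_ids == ["b"] and sub.outcome.tolist() == [1]
    r = t.restrict(["y"])
    assert r.feature_ids == ["y"] and r.values.tolist() == [[2.0], [4.0]]


def test_select_layers_keeps_covariates():
    t = bo.simulate_cohort(bo.CohortSpec(n_controls=12, n_cases=8, n_taxa=3,
                                         n_metabolites=3, seed=0))
    mic = t.select_layers(["microbiome"])
    assert set(mic.layers) == {bo.MICROBIOME, bo.COVARIATE}
    mic2 = t.select_layers(["microbiome"], keep_covariates=False)
    assert set(mic2.layers) == {bo.MICROBIOME}


# --- RNA-seq count simulator -------------------------------------------------

def test_simulate_counts_shapes_and_fold_change():
    counts, labels = bo.simulate_counts(100, 50, 20,
                                        fold_changes={"G0001": 8.0,
                                                      "G0002": 0.125},
                                        seed=3)
    assert counts.shape == (100, 70)
    assert labels.tolist() == [0] * 50 + [1] * 20
    c = counts.to_numpy()
    assert c[0, 50:].mean() > 3 * c[0, :50].mean()
    assert c[1, 50:].mean() < c[1, :50].mean() / 3


def test_simulate_counts_validation():
    with pytest.raises(KeyError, match="G9999"):
        bo.simulate_counts(10, 5, 5, fold_changes={"G9999": 2.0})
    with pytest.raises(ValueError):
        bo.simulate_counts(10, 5, 5, fold_changes={"G0001": -1.0})
    with pytest.raises(ValueError):
        bo.simulate_counts(10, 5, 5, dispersion=0.0)
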