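import numpy as np
import pytest

import bartomics as bo


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with one strong planted metabolite main effect."""
    spec = bo.CohortSpec(n_controls=40, n_cases=35, n_taxa=8, n_metabolites=8,
                         main_effects=(("M1", 2.0),), seed=11)
    return bo.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_posterior(small_cohort):
    cfg = bo.BartConfig(m=10, n_burn=50, n_post=60, seed=7)
    return bo.fit_probit(small_cohort, cfg)


@pytest.fixture(scope="session")
def hand_forest_posterior():
    """Posterior built from hand-written forests (two draws, two trees)."""
    t1 = bo.split(0, 0.5, bo.leaf(-1.0), bo.stump(1, 0.2, 0.5, 1.5))
    t2 = bo.stump(2, 0.0, -0.3, 0.3)
    t3 = bo.split(1, 0.1, bo.stump(0, 0.7, 0.0, 0.2), bo.leaf(1.0))
    t4 = bo.leaf(0.25)
    draws = [bo.SumOfTrees([t1, t2]), bo.SumOfTrees([t3, t4])]
    return bo.BartPosterior.from_forests(draws, ["f0", "f1", "f2"],
                                         offset=0.1)
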